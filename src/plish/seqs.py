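"""Sequence primitives shared across the probe-design stack.

Transcript coordinates are 1-based inclusive throughout the public API, matching
the convention used on probe order sheets ("nucleotides 347-386" is a 40-nt
site). Internal slicing uses Python half-open indices but never leaks them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (strict ACGT alphabet)."""
    bad = set(seq.upper()) - DNA_ALPHABET
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and map U->T so RNA input becomes the DNA working alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        raise ValueError(f"unsupported characters in sequence: {sorted(bad)}")
    return s


@dataclass(frozen=True)
class Transcript:
    """A target or background transcript, stored as DNA (U mapped to T)."""

    id: str
    sequence: str
    role: Literal["target", "background"] = "target"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        object.__setattr__(self, "sequence", normalize_rna(self.sequence))
        if not self.sequence:
            raise ValueError(f"transcript {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Subsequence by 1-based inclusive coordinates."""
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(
                f"coordinates {start}-{end} out of range for transcript "
                f"{self.id!r} of length {len(self.sequence)}"
            )
        return self.sequence[start - 1 : end]


def read_fasta(path: str | Path, role: Literal["target", "background"]) -> list[Transcript]:
    """Read a FASTA file into Transcript records, normalizing U->T."""
    records = [
        Transcript(id=rec.id, sequence=str(rec.seq), role=role)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(path: str | Path, transcripts: Iterable[Transcript]) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n")
            for i in range(0, len(t.sequence), 70):
                fh.write(t.sequence[i : i + 70] + "\n")


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        best = max(best, run)
    return best


def kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}
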