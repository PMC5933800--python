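"""FASTA input, validation, repeat filtering and the base encoding.

Bases are encoded as small integers: A=0, C=1, G=2, T=3, N=4.  Lowercase
letters in the source FASTA are taken as soft-masked (repeat-masked) bases:
they are case-folded to ordinary bases for modelling, but counted in
``masked_count`` so that heavily repetitive regions can be discarded.  Any
IUPAC ambiguity code other than A/C/G/T is mapped to N and likewise counted
as masked.

Internal coordinates are 0-based half-open throughout the package; written
output uses 1-based inclusive coordinates (see :mod:`motifmix.cli_report`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Union

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: integer codes for the DNA alphabet used everywhere in the package
BASE_A, BASE_C, BASE_G, BASE_T, BASE_N = 0, 1, 2, 3, 4
ALPHABET = "ACGTN"
#: complement lookup for encoded bases (N is self-complementary)
COMPLEMENT = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _ch in enumerate("ACGT"):
    _ENCODE[ord(_ch)] = _i
# ambiguity codes (and N itself) map to N
for _ch in "NRYSWKMBDHV":
    if _ENCODE[ord(_ch)] == 255:
        _ENCODE[ord(_ch)] = BASE_N
_ENCODE[ord("N")] = BASE_N


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass
class EncodedSequence:
    """One input sequence with its integer-encoded bases.

    Attributes
    ----------
    id : str
        Record identifier from the FASTA header.
    bases : np.ndarray
        uint8 vector of codes over {A,C,G,T,N}.
    masked_count : int
        Number of source bases that were lowercase (soft-masked) or
        ambiguity codes.
    """

    id: str
    bases: np.ndarray
    masked_count: int = 0

    def __post_init__(self) -> None:
        self.bases = np.asarray(self.bases, dtype=np.uint8)
        if self.bases.size < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.bases.max(initial=0) > BASE_N:
            raise ValueError(f"sequence {self.id!r} contains invalid base codes")
        if self.masked_count > self.bases.size:
            raise ValueError(f"sequence {self.id!r}: masked_count exceeds length")

    @property
    def length(self) -> int:
        return int(self.bases.size)

    def text(self) -> str:
        """Decode back to an A/C/G/T/N string."""
        return "".join(ALPHABET[b] for b in self.bases)

    @classmethod
    def from_text(cls, id: str, seq: str) -> "EncodedSequence":
        raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        upper = np.where((raw >= ord("a")) & (raw <= ord("z")), raw - 32, raw)
        codes = _ENCODE[upper]
        if np.any(codes == 255):
            bad = chr(int(upper[codes == 255][0]))
            raise FastaParseError(f"sequence {id!r}: invalid character {bad!r}")
        lowercase = int(np.sum(raw != upper))
        # uppercase N or ambiguity codes also count as masked; lowercase ones
        # are already counted once via the lowercase tally
        upper_n = int(np.sum((codes == BASE_N) & (raw == upper)))
        return cls(id=id, bases=codes, masked_count=lowercase + upper_n)


@dataclass
class SequenceSet:
    """Ordered collection of :class:`EncodedSequence` with unique ids."""

    sequences: List[EncodedSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.id for s in self.sequences]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence ids: {dupes[:5]}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return iter(self.sequences)

    def __getitem__(self, i: int) -> EncodedSequence:
        return self.sequences[i]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([s.length for s in self.sequences], dtype=np.int64)


def read_fasta(path: Union[str, Path]) -> SequenceSet:
    """Read a (possibly line-wrapped) multi-record FASTA file.

    Letters are case-folded to upper case; lowercase source letters and
    IUPAC ambiguity codes are tallied in each record's ``masked_count``.

    Raises
    ------
    FastaParseError
        If the file contains sequence data before any ``>`` header (the
        offending line number is reported) or contains no records.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: sequence data before any '>' header"
                )
            break
        else:
            raise FastaParseError(f"{path}: no sequences found")

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(EncodedSequence.from_text(rec.id, str(rec.seq)))
    if not records:
        raise FastaParseError(f"{path}: no sequences found")
    return SequenceSet(records)


def write_fasta(sset: SequenceSet, path: Union[str, Path], width: int = 70) -> None:
    """Write the set back out as plain FASTA (upper-case, N for masked)."""
    with open(path, "w") as fh:
        for seq in sset:
            fh.write(f">{seq.id}\n")
            text = seq.text()
            for i in range(0, len(text), width):
                fh.write(text[i : i + width] + "\n")


def filter_repeats(
    sset: SequenceSet, max_masked: int = 150, min_length: int = 1
) -> SequenceSet:
    """Drop heavily repeat-masked or too-short sequences.

    Keeps sequences with ``masked_count <= max_masked`` and
    ``length >= min_length``, preserving input order.  ``min_length`` should
    be at least the maximum motif width under consideration so that every
    retained sequence admits at least one site for every mode.
    """
    if max_masked < 0:
        raise ValueError("max_masked must be >= 0")
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [
        s for s in sset if s.masked_count <= max_masked and s.length >= min_length
    ]
    removed = sset.n - len(kept)
    if removed:
        logger.info("filter_repeats: removed %d of %d sequences", removed, sset.n)
    if not kept:
        raise ValueError(
            "all sequences filtered out "
            f"(max_masked={max_masked}, min_length={min_length})"
        )
    return SequenceSet(kept)
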