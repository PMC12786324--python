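"""Sequence input/output and TSS-anchored promoter coordinate handling.

Genomic coordinates entering or leaving this module are 1-based inclusive
(NCBI style); everything internal is 0-based half-open.  A promoter window of
length ``L`` extracted upstream of a transcription start site (TSS) covers
TSS-relative positions ``-L .. -1``: position ``-1`` is the base immediately
5' of the TSS and the TSS base itself is never included.  The extracted
sequence always reads 5'->3' toward the TSS regardless of the gene's strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

from .errors import FastaParseError, RangeError

__all__ = [
    "SeqRecord",
    "PromoterRegion",
    "read_fasta",
    "write_fasta",
    "extract_promoter",
    "reverse_complement",
    "encode_bases",
    "decode_bases",
]

# IUPAC ambiguity codes other than N are collapsed to N at load: the scanners
# define behaviour only over {A,C,G,T,N}.
_AMBIGUITY = "RYSWKMBDHV"
_NORMALIZE = str.maketrans("U" + _AMBIGUITY, "T" + "N" * len(_AMBIGUITY))
_VALID_AFTER = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# A=0, C=1, G=2, T=3, N=4 — shared numeric alphabet for vectorised scanning.
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGTN"):
    _ENCODE[_b] = _i
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


@dataclass(frozen=True)
class SeqRecord:
    """A named nucleotide sequence over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FastaParseError(f"record {self.id!r}: empty sequence")
        bad = _VALID_AFTER.search(self.sequence)
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: illegal character {bad.group()!r} "
                f"at offset {bad.start()}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PromoterRegion:
    """An upstream promoter window anchored at a TSS.

    ``sequence`` is written 5'->3' toward the TSS, so index ``i`` (0-based)
    corresponds to TSS-relative position ``r = i - length``.
    """

    source_id: str
    tss_genomic: int
    strand: str
    length: int
    sequence: str
    assembly_label: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.sequence) != self.length:
            raise ValueError(
                f"sequence length {len(self.sequence)} != declared length {self.length}"
            )

    def rel_to_index(self, rel: int) -> int:
        """Map a TSS-relative position in [-L, -1] to a 0-based index."""
        return rel_to_index(self.length, rel)

    def index_to_rel(self, i: int) -> int:
        """Map a 0-based index in [0, L) to a TSS-relative position."""
        return index_to_rel(self.length, i)

    def genomic_interval(self) -> tuple[int, int]:
        """1-based inclusive genomic interval covered by the window."""
        if self.strand == "+":
            return (self.tss_genomic - self.length, self.tss_genomic - 1)
        return (self.tss_genomic + 1, self.tss_genomic + self.length)


def rel_to_index(length: int, rel: int) -> int:
    if not -length <= rel <= -1:
        raise RangeError(
            f"TSS-relative position {rel} outside [-{length}, -1]"
        )
    return rel + length


def index_to_rel(length: int, i: int) -> int:
    if not 0 <= i < length:
        raise RangeError(f"index {i} outside [0, {length})")
    return i - length


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_bases(seq: str) -> np.ndarray:
    """Encode a {A,C,G,T,N} string as a uint8 array (A=0..T=3, N=4)."""
    arr = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if arr.max(initial=0) == 255:
        bad = int(np.argmax(arr == 255))
        raise ValueError(f"illegal character {seq[bad]!r} at offset {bad}")
    return arr


def decode_bases(arr: np.ndarray) -> str:
    return _DECODE[arr].tobytes().decode("ascii")


def _normalize(raw: str, record_id: str) -> str:
    seq = raw.upper().translate(_NORMALIZE)
    bad = _VALID_AFTER.search(seq)
    if bad:
        raise FastaParseError(
            f"record {record_id!r}: illegal character {raw[bad.start()]!r} "
            f"at offset {bad.start()}"
        )
    return seq


def read_fasta(path) -> list[SeqRecord]:
    """Read a (multi-)FASTA file into normalized records.

    Sequences are uppercased, U is mapped to T and IUPAC ambiguity codes are
    collapsed to N.  Any other character raises :class:`FastaParseError`
    naming the record and offset.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            SeqRecord(
                id=rec.id,
                sequence=_normalize(str(rec.seq), rec.id),
                description=rec.description,
            )
        )
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def extract_promoter(
    record: SeqRecord,
    tss_genomic: int,
    upstream_len: int,
    strand: str = "+",
    assembly_label: str = "",
) -> PromoterRegion:
    """Extract the ``upstream_len`` bases immediately 5' of a TSS.

    On the + strand this is the genomic interval
    ``[tss_genomic - upstream_len, tss_genomic - 1]`` (1-based inclusive),
    returned as-is; on the - strand it is the reverse complement of
    ``[tss_genomic + 1, tss_genomic + upstream_len]``.  Either way the result
    reads 5'->3' toward the TSS and excludes the TSS base.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    if upstream_len < 1:
        raise ValueError("upstream_len must be >= 1")
    n = len(record.sequence)
    if strand == "+":
        start = tss_genomic - upstream_len  # 1-based
        if start < 1 or tss_genomic - 1 > n:
            raise RangeError(
                f"requested genomic interval [{start}, {tss_genomic - 1}] "
                f"outside available [1, {n}] of record {record.id!r}"
            )
        seq = record.sequence[start - 1 : tss_genomic - 1]
    else:
        end = tss_genomic + upstream_len
        if tss_genomic + 1 < 1 or end > n:
            raise RangeError(
                f"requested genomic interval [{tss_genomic + 1}, {end}] "
                f"outside available [1, {n}] of record {record.id!r}"
            )
        seq = reverse_complement(record.sequence[tss_genomic : end])
    return PromoterRegion(
        source_id=record.id,
        tss_genomic=tss_genomic,
        strand=strand,
        length=upstream_len,
        sequence=seq,
        assembly_label=assembly_label,
    )


def region_from_sequence(
    sequence: str,
    source_id: str = "promoter",
    tss_genomic: int | None = None,
    strand: str = "+",
    assembly_label: str = "",
) -> PromoterRegion:
    """Wrap a bare promoter sequence as a PromoterRegion.

    When no genomic anchor is known the TSS is placed at ``len(sequence)+1``,
    i.e. immediately 3' of the window on a virtual + strand contig.
    """
    L = len(sequence)
    return PromoterRegion(
        source_id=source_id,
        tss_genomic=L + 1 if tss_genomic is None else tss_genomic,
        strand=strand,
        length=L,
        sequence=sequence,
        assembly_label=assembly_label,
    )
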