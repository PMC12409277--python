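"""Core record types shared across pipeline stages, plus FASTQ/SAM I/O helpers.

Reads are carried as lightweight :class:`ReadRecord` objects; alignments as
:class:`AlignmentRecord`. Coordinates are 0-based half-open internally;
files are emitted per their format standards (FASTQ phred+33, SAM 1-based).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class ReadRecord:
    """A sequenced fragment: id, bases over {A,C,G,T,N}, per-base phred."""

    read_id: str
    seq: str
    qual: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.read_id}: seq length {len(self.seq)} != "
                f"qual length {len(self.qual)}"
            )

    @property
    def mean_quality(self) -> float:
        return sum(self.qual) / len(self.qual) if self.qual else 0.0


@dataclass
class AlignmentRecord:
    """One placement of a read on a reference.

    ``seq`` is stored in reference orientation (as in SAM); ``md`` encodes
    the reference bases under the alignment; ``nm`` is the edit distance.
    """

    read_id: str
    ref_id: str
    pos: int  # 0-based start on the reference
    strand: str  # '+' or '-'
    cigar: str
    nm: int
    mapq: int
    seq: str
    md: str | None = None

    @property
    def aligned_length(self) -> int:
        return len(self.seq)

    @property
    def end(self) -> int:
        return self.pos + len(self.seq)


def phred_to_ascii(quals: Sequence[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def ascii_to_phred(s: str) -> list[int]:
    return [ord(c) - 33 for c in s]


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{phred_to_ascii(r.qual)}\n")
            n += 1
    return n


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()  # separator
            qual = fh.readline().strip()
            yield ReadRecord(header.strip()[1:].split()[0], seq, ascii_to_phred(qual))


def make_md_tag(read_ref_oriented: str, ref_slice: str) -> tuple[str, int]:
    """Build the MD tag and NM count for an ungapped alignment."""
    md_parts: list[str] = []
    match_run = 0
    nm = 0
    for rb, fb in zip(read_ref_oriented, ref_slice):
        if rb == fb:
            match_run += 1
        else:
            md_parts.append(str(match_run))
            md_parts.append(fb)
            match_run = 0
            nm += 1
    md_parts.append(str(match_run))
    return "".join(md_parts), nm


def write_sam(
    alignments: Iterable[AlignmentRecord],
    ref_lengths: dict[str, int],
    path: str | Path,
) -> int:
    """Write alignments as plain-text SAM with NM and MD tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in ref_lengths.items()],
    }
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln in alignments:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = aln.read_id
            seg.query_sequence = aln.seq
            seg.flag = 16 if aln.strand == "-" else 0
            seg.reference_id = out.header.get_tid(aln.ref_id)
            seg.reference_start = aln.pos
            seg.mapping_quality = aln.mapq
            seg.cigarstring = aln.cigar
            tags = [("NM", aln.nm)]
            if aln.md is not None:
                tags.append(("MD", aln.md))
            seg.set_tags(tags)
            out.write(seg)
            n += 1
    return n


def read_sam(path: str | Path) -> Iterator[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        yield from fh


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:]
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out
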