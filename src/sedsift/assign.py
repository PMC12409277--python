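"""Competitive read assignment among phylogenetically close candidate
references, and the per-taxon mapping statistics summary.

Each read aligned against several candidate genomes is awarded to the
alignment with the smallest edit distance (NM); ties on NM fall back to
mapping quality, and reads still tied are discarded as unassignable —
authentication favours specificity over yield. Winners below the mapping
quality floor (default 30) are likewise not assigned.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pysam

from .core import AlignmentRecord

UNASSIGNED_TIE = "tie"
UNASSIGNED_MAPQ = "below_mapq"
UNASSIGNED_NOHIT = "no_hit"


@dataclass
class AssignmentResult:
    assigned: dict[str, str]  # read_id -> winning ref_id
    unassigned: dict[str, str]  # read_id -> reason

    def reason_counts(self) -> dict[str, int]:
        counts = {UNASSIGNED_TIE: 0, UNASSIGNED_MAPQ: 0, UNASSIGNED_NOHIT: 0}
        for reason in self.unassigned.values():
            counts[reason] += 1
        return counts

    @property
    def n_total(self) -> int:
        return len(self.assigned) + len(self.unassigned)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"read_id": rid, "ref_id": ref, "status": "assigned"}
            for rid, ref in self.assigned.items()
        ] + [
            {"read_id": rid, "ref_id": "", "status": reason}
            for rid, reason in self.unassigned.items()
        ]
        return pd.DataFrame(rows, columns=["read_id", "ref_id", "status"])


def assign_reads(
    alignments: list[AlignmentRecord],
    min_mapq: int = 30,
    all_read_ids: list[str] | None = None,
) -> AssignmentResult:
    """Assign each read to its minimal-edit-distance reference.

    ``all_read_ids``, when given, declares the full read universe so reads
    with no alignment at all are reported as no_hit; the partition
    assigned + tie + below_mapq + no_hit always covers every read exactly
    once.
    """
    by_read: dict[str, list[AlignmentRecord]] = defaultdict(list)
    seen_pairs: set[tuple[str, str]] = set()
    for aln in alignments:
        key = (aln.read_id, aln.ref_id)
        if key in seen_pairs:
            raise ValueError(
                f"duplicate alignment for read {aln.read_id} on {aln.ref_id}; "
                "deduplicate input first"
            )
        seen_pairs.add(key)
        by_read[aln.read_id].append(aln)

    assigned: dict[str, str] = {}
    unassigned: dict[str, str] = {}
    for read_id, alns in by_read.items():
        best_nm = min(a.nm for a in alns)
        best = [a for a in alns if a.nm == best_nm]
        if len(best) > 1:
            best_mapq = max(a.mapq for a in best)
            best = [a for a in best if a.mapq == best_mapq]
        if len(best) > 1:
            unassigned[read_id] = UNASSIGNED_TIE
        elif best[0].mapq < min_mapq:
            unassigned[read_id] = UNASSIGNED_MAPQ
        else:
            assigned[read_id] = best[0].ref_id

    if all_read_ids is not None:
        for rid in all_read_ids:
            if rid not in assigned and rid not in unassigned:
                unassigned[rid] = UNASSIGNED_NOHIT
    return AssignmentResult(assigned=assigned, unassigned=unassigned)


@dataclass
class TaxonMapStats:
    """One row of per-taxon mapping statistics: mapped read count, mean
    terminal damage over the last 3 bp, mean edit distance, and mean depth
    of coverage (aligned bases / genome length)."""

    ref_id: str
    mapped_reads: int
    av_edit_distance: float | None
    average_coverage: float | None
    av_damage_last3: float | None = None

    def as_dict(self) -> dict:
        return {
            "ref_id": self.ref_id,
            "mapped_reads": self.mapped_reads,
            "av_damage_last3": self.av_damage_last3,
            "av_edit_distance": self.av_edit_distance,
            "average_coverage": self.average_coverage,
        }


def taxon_stats(
    result: AssignmentResult,
    alignments: list[AlignmentRecord],
    genome_lengths: dict[str, int],
    damage_last3: dict[str, float] | None = None,
) -> list[TaxonMapStats]:
    """Per-reference mapping statistics over assigned reads only.

    ``damage_last3`` is the terminal-damage summary per reference computed
    by the damage module; references with no assigned reads report zero
    mapped reads and absent (None) statistics rather than NaN.
    """
    aln_lookup = {(a.read_id, a.ref_id): a for a in alignments}
    per_ref: dict[str, list[AlignmentRecord]] = defaultdict(list)
    for read_id, ref_id in result.assigned.items():
        per_ref[ref_id].append(aln_lookup[(read_id, ref_id)])

    out = []
    for ref_id, length in genome_lengths.items():
        if length <= 0:
            raise ValueError(f"genome length for {ref_id} must be positive")
        alns = per_ref.get(ref_id, [])
        if not alns:
            out.append(TaxonMapStats(ref_id, 0, None, None, None))
            continue
        out.append(
            TaxonMapStats(
                ref_id=ref_id,
                mapped_reads=len(alns),
                av_edit_distance=sum(a.nm for a in alns) / len(alns),
                average_coverage=sum(a.aligned_length for a in alns) / length,
                av_damage_last3=(damage_last3 or {}).get(ref_id),
            )
        )
    return out


def alignments_from_sam(path: str | Path) -> list[AlignmentRecord]:
    """Load mapped records from a SAM file into AlignmentRecords."""
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped:
                continue
            out.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    ref_id=seg.reference_name,
                    pos=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    cigar=seg.cigarstring,
                    nm=seg.get_tag("NM") if seg.has_tag("NM") else 0,
                    mapq=seg.mapping_quality,
                    seq=seg.query_sequence,
                    md=seg.get_tag("MD") if seg.has_tag("MD") else None,
                )
            )
    return out
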