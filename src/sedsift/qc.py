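"""Read-level preprocessing: length/quality filters, DUST low-complexity
removal, and exact-sequence deduplication, applied in that fixed order.

The DUST statistic is the windowed overlapping-triplet score: for each 64 bp
window (stepped by 32 bp; the whole read when shorter),

    score_w = 100 * sum_t c_t (c_t - 1) / 2  /  ((w - 3)(w - 2) / 2)

where c_t counts occurrences of triplet t in the window, and the read score
is the maximum over windows. A homopolymer scores 100; a window of all
distinct triplets scores 0. Reads scoring above the threshold (default 7)
are removed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .core import ReadRecord

DUST_WINDOW = 64
DUST_STEP = 32


@dataclass
class QCParams:
    min_len: int = 30
    min_mean_q: float = 20.0
    dust_threshold: float = 7.0
    dedup: bool = True

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if not (0.0 <= self.dust_threshold <= 100.0):
            raise ValueError("dust_threshold must lie in [0, 100]")


@dataclass
class QCReport:
    """Removal counts per filter, in application order."""

    n_input: int = 0
    removed_length: int = 0
    removed_quality: int = 0
    removed_dust: int = 0
    removed_duplicate: int = 0
    n_kept: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "input": self.n_input,
            "removed_length": self.removed_length,
            "removed_quality": self.removed_quality,
            "removed_dust": self.removed_dust,
            "removed_duplicate": self.removed_duplicate,
            "kept": self.n_kept,
        }

    def reconciles(self) -> bool:
        return self.n_input == self.n_kept + (
            self.removed_length
            + self.removed_quality
            + self.removed_dust
            + self.removed_duplicate
        )


def _window_score(window: str) -> float:
    w = len(window)
    counts = Counter(window[i : i + 3] for i in range(w - 2))
    numer = sum(c * (c - 1) // 2 for c in counts.values())
    denom = (w - 3) * (w - 2) / 2
    return 100.0 * numer / denom if denom > 0 else 0.0


def dust_score(seq: str) -> float:
    """Low-complexity score in [0, 100]; max over 64 bp windows."""
    if len(seq) < 3:
        raise ValueError("sequence shorter than 3 bp has no triplets")
    if len(seq) <= DUST_WINDOW:
        return _window_score(seq)
    best = 0.0
    starts = list(range(0, len(seq) - DUST_WINDOW + 1, DUST_STEP))
    if starts[-1] != len(seq) - DUST_WINDOW:
        starts.append(len(seq) - DUST_WINDOW)
    for s in starts:
        best = max(best, _window_score(seq[s : s + DUST_WINDOW]))
    return best


def dedup(reads: list[ReadRecord]) -> list[ReadRecord]:
    """Collapse exact duplicate sequences.

    Survivor per sequence is the record with the highest mean quality;
    ties keep the first occurrence. Output order follows first occurrence.
    """
    best: dict[str, ReadRecord] = {}
    order: list[str] = []
    for r in reads:
        cur = best.get(r.seq)
        if cur is None:
            best[r.seq] = r
            order.append(r.seq)
        elif r.mean_quality > cur.mean_quality:
            best[r.seq] = r
    return [best[s] for s in order]


def qc_filter(
    reads: list[ReadRecord], params: QCParams | None = None
) -> tuple[list[ReadRecord], QCReport]:
    """Apply length -> mean-quality -> DUST -> dedup; attribute each removal
    to the first violated filter."""
    params = params or QCParams()
    report = QCReport(n_input=len(reads))
    kept: list[ReadRecord] = []
    for r in reads:
        if len(r.seq) < params.min_len:
            report.removed_length += 1
        elif r.mean_quality < params.min_mean_q:
            report.removed_quality += 1
        elif dust_score(r.seq) > params.dust_threshold:
            report.removed_dust += 1
        else:
            kept.append(r)
    if params.dedup:
        unique = dedup(kept)
        report.removed_duplicate = len(kept) - len(unique)
        kept = unique
    report.n_kept = len(kept)
    return kept, report
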