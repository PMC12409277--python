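"""Post-mortem damage profiling and authentication statistics.

Ancient DNA carries terminal cytosine deamination: an excess of C>T
substitutions at the 5' end of fragments (and G>A at the 3' end in
double-stranded libraries) that decays with distance from the fragment end.
This module tallies position-specific misincorporation counts against the
reference (reconstructed from MD tags or a supplied FASTA), summarises
terminal damage over the last k bases, computes fragment-length /
edit-distance / GC distributions, and compares damage levels between groups
of taxa (Welch's t-test for two groups, one-way ANOVA plus per-group
contrasts against a reference group otherwise).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import AlignmentRecord

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
SUBSTITUTIONS = [
    (r, q) for r in "ACGT" for q in "ACGT" if r != q
]

_MD_TOKEN = re.compile(r"(\d+)|\^([A-Za-z]+)|([A-Za-z])")
_CIGAR_TOKEN = re.compile(r"(\d+)([MIDNSHP=X])")


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_TOKEN.findall(cigar)]


def reference_from_md(seq: str, cigar: str, md: str) -> list[tuple[str, str]]:
    """Reconstruct (read_base, ref_base) pairs over aligned columns.

    Follows the SAM conventions: MD runs over aligned reference bases (M and
    D cigar ops), insertions contribute read bases with no reference and are
    skipped, deletions advance the reference only, soft clips advance the
    read only. Returned pairs cover aligned (M/=/X) columns in reference
    orientation.
    """
    md_events: list[tuple[str, str]] = []  # ('match', n) | ('mismatch', base) | ('del', bases)
    for num, deletion, base in _MD_TOKEN.findall(md):
        if num:
            md_events.append(("match", num))
        elif deletion:
            md_events.append(("del", deletion))
        else:
            md_events.append(("mismatch", base))

    # Flatten MD into a per-aligned-reference-base iterator of ref bases
    # (None means "same as read base").
    ref_bases: list[str | None] = []
    for kind, payload in md_events:
        if kind == "match":
            ref_bases.extend([None] * int(payload))
        elif kind == "mismatch":
            ref_bases.append(payload.upper())
        else:  # deleted reference bases: consumed by D ops below
            ref_bases.extend(list(payload.upper()))

    pairs: list[tuple[str, str]] = []
    read_i = 0
    md_i = 0
    for n, op in _parse_cigar(cigar):
        if op in "M=X":
            for _ in range(n):
                rb = seq[read_i]
                fb = ref_bases[md_i]
                pairs.append((rb, rb if fb is None else fb))
                read_i += 1
                md_i += 1
        elif op == "I":
            read_i += n
        elif op == "D":
            md_i += n
        elif op == "S":
            read_i += n
        # N/H/P do not occur in this pipeline's alignments
    return pairs


def reference_from_fasta(
    aln: AlignmentRecord, references: dict[str, str]
) -> list[tuple[str, str]]:
    """(read_base, ref_base) pairs using an explicit reference sequence."""
    ref_seq = references[aln.ref_id]
    pairs: list[tuple[str, str]] = []
    read_i, ref_i = 0, aln.pos
    for n, op in _parse_cigar(aln.cigar):
        if op in "M=X":
            for _ in range(n):
                pairs.append((aln.seq[read_i], ref_seq[ref_i]))
                read_i += 1
                ref_i += 1
        elif op == "I":
            read_i += n
        elif op == "D":
            ref_i += n
        elif op == "S":
            read_i += n
    return pairs


@dataclass
class DamageProfile:
    """Position-wise misincorporation counts from both fragment ends.

    ``counts[(end, pos, ref, read)]`` tallies substitutions and
    ``opportunities[(end, pos, ref)]`` reference-base occurrences, for end
    in {'5p','3p'} and 1-based position 1..n_positions counted inward from
    that end in read orientation.
    """

    n_positions: int = 30
    counts: dict = field(default_factory=dict)
    opportunities: dict = field(default_factory=dict)
    n_reads: int = 0
    n_skipped: int = 0

    def frequency(self, end: str, pos: int, ref: str, read: str) -> float:
        opp = self.opportunities.get((end, pos, ref), 0)
        if opp == 0:
            return float("nan")
        return self.counts.get((end, pos, ref, read), 0) / opp

    def add(self, other: "DamageProfile") -> "DamageProfile":
        if self.n_positions != other.n_positions:
            raise ValueError("profiles differ in n_positions")
        merged = DamageProfile(self.n_positions)
        merged.n_reads = self.n_reads + other.n_reads
        merged.n_skipped = self.n_skipped + other.n_skipped
        for src in (self, other):
            for k, v in src.counts.items():
                merged.counts[k] = merged.counts.get(k, 0) + v
            for k, v in src.opportunities.items():
                merged.opportunities[k] = merged.opportunities.get(k, 0) + v
        return merged

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for end in ("5p", "3p"):
            for pos in range(1, self.n_positions + 1):
                for ref, read in SUBSTITUTIONS:
                    opp = self.opportunities.get((end, pos, ref), 0)
                    cnt = self.counts.get((end, pos, ref, read), 0)
                    rows.append(
                        {
                            "end": end,
                            "position": pos,
                            "substitution": f"{ref}>{read}",
                            "count": cnt,
                            "opportunities": opp,
                            "frequency": cnt / opp if opp else float("nan"),
                        }
                    )
        return pd.DataFrame(rows)


def misincorporation_profile(
    alignments: list[AlignmentRecord],
    n_positions: int = 30,
    references: dict[str, str] | None = None,
) -> DamageProfile:
    """Tally all 12 substitution types by distance from each fragment end.

    Minus-strand alignments are complement-reversed into read orientation
    first, so position 1 at the 5' end is always the first sequenced base.
    Reference bases come from MD tags when present, else from ``references``;
    alignments providing neither are skipped and counted in ``n_skipped``.
    """
    profile = DamageProfile(n_positions=n_positions)
    for aln in alignments:
        if aln.md is not None:
            pairs = reference_from_md(aln.seq, aln.cigar, aln.md)
        elif references is not None and aln.ref_id in references:
            pairs = reference_from_fasta(aln, references)
        else:
            profile.n_skipped += 1
            continue
        if aln.strand == "-":
            pairs = [
                (COMPLEMENT[rb], COMPLEMENT[fb]) for rb, fb in reversed(pairs)
            ]
        n = len(pairs)
        profile.n_reads += 1
        for i, (read_b, ref_b) in enumerate(pairs):
            if ref_b not in "ACGT" or read_b not in "ACGT":
                continue
            p5 = i + 1
            p3 = n - i
            for end, pos in (("5p", p5), ("3p", p3)):
                if pos <= n_positions:
                    key_opp = (end, pos, ref_b)
                    profile.opportunities[key_opp] = (
                        profile.opportunities.get(key_opp, 0) + 1
                    )
                    if read_b != ref_b:
                        key = (end, pos, ref_b, read_b)
                        profile.counts[key] = profile.counts.get(key, 0) + 1
    return profile


@dataclass
class DamageSummary:
    """Opportunity-weighted mean deamination over the terminal k positions
    (5' C>T and 3' G>A cells pooled), with the minimum-read-support gate."""

    k: int
    value: float | None
    n_reads: int
    gate_passed: bool


def terminal_damage(
    profile: DamageProfile, k: int = 3, min_reads: int = 100
) -> DamageSummary:
    """Average deamination in the last k bases of both read ends.

    Pools 5' C>T counts at positions 1..k with 3' G>A counts at positions
    1..k, weighting by opportunities. The support gate requires strictly
    more than ``min_reads`` reads.
    """
    num = 0
    den = 0
    for i in range(1, k + 1):
        num += profile.counts.get(("5p", i, "C", "T"), 0)
        num += profile.counts.get(("3p", i, "G", "A"), 0)
        den += profile.opportunities.get(("5p", i, "C"), 0)
        den += profile.opportunities.get(("3p", i, "G"), 0)
    value = num / den if den else None
    return DamageSummary(
        k=k,
        value=value,
        n_reads=profile.n_reads,
        gate_passed=profile.n_reads > min_reads,
    )


def distributions(alignments: list[AlignmentRecord]) -> dict[str, pd.Series]:
    """Read-length, edit-distance and GC-content tables.

    GC is computed per read over A/C/G/T (N excluded); lengths are aligned
    read lengths in read orientation.
    """
    lengths = pd.Series([len(a.seq) for a in alignments], dtype=int)
    edits = pd.Series([a.nm for a in alignments], dtype=int)
    gc = []
    for a in alignments:
        acgt = sum(a.seq.count(b) for b in "ACGT")
        gc.append((a.seq.count("G") + a.seq.count("C")) / acgt if acgt else np.nan)
    return {
        "length": lengths.value_counts().sort_index(),
        "edit_distance": edits.value_counts().sort_index(),
        "gc": pd.Series(gc, dtype=float),
    }


@dataclass
class GroupComparison:
    test: str  # 'welch-t' or 'anova'
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    contrasts: pd.DataFrame | None = None  # per-group Welch vs reference


def compare_damage(
    groups: dict[str, list[float]], reference_group: str | None = None
) -> GroupComparison:
    """Compare damage levels across groups.

    Two groups: Welch's unequal-variance t-test with Welch-Satterthwaite
    degrees of freedom. More than two: one-way ANOVA, plus pairwise Welch
    contrasts of every group against ``reference_group`` when given.
    Groups with fewer than two values are excluded with a warning.
    """
    usable = {}
    for name, values in groups.items():
        if len(values) < 2:
            warnings.warn(
                f"group {name!r} has <2 values and is excluded", stacklevel=2
            )
        else:
            usable[name] = np.asarray(values, dtype=float)
    if len(usable) < 2:
        raise ValueError("need at least two groups with >=2 values each")

    if len(usable) == 2:
        (na, a), (nb, b) = usable.items()
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupComparison(
            test="welch-t",
            statistic=float(res.statistic),
            df=float(res.df),
            p_value=float(res.pvalue),
        )

    res = stats.f_oneway(*usable.values())
    k = len(usable)
    n_total = sum(len(v) for v in usable.values())
    contrasts = None
    if reference_group is not None:
        if reference_group not in usable:
            raise ValueError(f"reference group {reference_group!r} not usable")
        ref = usable[reference_group]
        rows = []
        for name, values in usable.items():
            if name == reference_group:
                continue
            t = stats.ttest_ind(values, ref, equal_var=False)
            rows.append(
                {
                    "group": name,
                    "reference": reference_group,
                    "statistic": float(t.statistic),
                    "df": float(t.df),
                    "p_value": float(t.pvalue),
                }
            )
        contrasts = pd.DataFrame(rows)
    return GroupComparison(
        test="anova",
        statistic=float(res.statistic),
        df=(float(k - 1), float(n_total - k)),
        p_value=float(res.pvalue),
        contrasts=contrasts,
    )


def fit_damage_model(
    profile: DamageProfile, n_fit: int = 10
) -> tuple[float, float, float]:
    """Recover (delta5, decay, floor) from the 5' C>T curve.

    Fits rate_i = floor + (peak - floor) * decay**(i-1) by least squares on
    positions 1..n_fit, weighting each position by its opportunity count.
    """
    from scipy.optimize import curve_fit

    pos = np.arange(1, n_fit + 1, dtype=float)
    freqs, weights = [], []
    for i in range(1, n_fit + 1):
        f = profile.frequency("5p", i, "C", "T")
        opp = profile.opportunities.get(("5p", i, "C"), 0)
        freqs.append(0.0 if np.isnan(f) else f)
        weights.append(max(opp, 1))
    freqs = np.asarray(freqs)
    sigma = 1.0 / np.sqrt(np.asarray(weights, dtype=float))

    def model(i, peak, decay, floor):
        return floor + (peak - floor) * decay ** (i - 1)

    popt, _ = curve_fit(
        model,
        pos,
        freqs,
        p0=(max(freqs[0], 0.05), 0.5, 0.01),
        sigma=sigma,
        bounds=([0.0, 1e-6, 0.0], [1.0, 1.0, 1.0]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])
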