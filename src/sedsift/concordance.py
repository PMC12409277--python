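"""Genotype-level comparison of two sequencing sources of one individual:
pseudohaploid calling, imputation post-filters, plink-style dosage hard
calls, phenotype-marker concordance, and the pairwise mismatch rate (P0)
used to flag identical/related sample pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1


def pseudohaploid_call(
    pileups: pd.DataFrame, panel: pd.DataFrame, seed: int
) -> pd.Series:
    """Draw one covering base per panel site, uniformly at random.

    ``panel`` has columns chrom, pos, ref, alt; ``pileups`` columns chrom,
    pos, A, C, G, T. Sites with zero coverage are missing; a drawn base
    matching neither panel allele is missing too (the draw is over observed
    bases so a third allele is sampled in proportion to its depth but never
    emitted as a call). Returns a Series indexed by (chrom, pos) with values
    in {'ref','alt',NA}.
    """
    rng = np.random.default_rng(seed)
    indexed = pileups.set_index(["chrom", "pos"])
    calls = {}
    for _, site in panel.iterrows():
        key = (site["chrom"], site["pos"])
        try:
            row = indexed.loc[key]
        except KeyError:
            calls[key] = pd.NA
            continue
        bases, weights = [], []
        for b in "ACGT":
            n = int(row[b])
            if n > 0:
                bases.append(b)
                weights.append(n)
        if not bases:
            calls[key] = pd.NA
            continue
        total = sum(weights)
        drawn = bases[rng.choice(len(bases), p=[w / total for w in weights])]
        if drawn == site["ref"]:
            calls[key] = "ref"
        elif drawn == site["alt"]:
            calls[key] = "alt"
        else:
            calls[key] = pd.NA
    return pd.Series(calls, dtype="object")


def imputation_filter(
    records: pd.DataFrame, min_maf: float = 0.05, min_gp: float = 0.98
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Post-imputation site filters: panel MAF >= min_maf and genotype
    probability GP >= min_gp (both inclusive).

    Records with missing GP fail and are tallied separately. Returns the
    retained records and removal counts per rule (first violated rule, in
    order maf -> gp)."""
    removed = {"missing_gp": 0, "maf": 0, "gp": 0}
    keep = []
    for i, rec in records.iterrows():
        if rec["panel_maf"] < min_maf:
            removed["maf"] += 1
        elif pd.isna(rec["gp"]):
            removed["missing_gp"] += 1
        elif rec["gp"] < min_gp:
            removed["gp"] += 1
        else:
            keep.append(i)
    return records.loc[keep], removed


def dosage_code(ds: float, hard_call_threshold: float = 0.1) -> int:
    """plink-style dosage hard call: the nearest integer genotype when the
    expected alternate dosage lies within the threshold of it, else missing
    (returned as -1)."""
    if not (0.0 <= ds <= 2.0):
        raise ValueError(f"dosage {ds} outside [0, 2]")
    nearest = round(ds)
    # 1e-9 slack keeps decimal boundaries (e.g. 1.9 vs 2) exact despite
    # binary float representation
    return int(nearest) if abs(ds - nearest) <= hard_call_threshold + 1e-9 else MISSING


@dataclass
class ConcordanceResult:
    n_markers: int
    n_compared: int
    n_discordant: int
    pct_concordant: float
    detail: pd.DataFrame


def phenotype_concordance(
    codes_a: pd.Series,
    codes_b: pd.Series,
    include_missing: bool = False,
) -> ConcordanceResult:
    """Genotype-code concordance over a shared marker panel.

    Both inputs are integer codes {0,1,2} with -1 for missing, indexed by
    marker. By default pairs with any missing code are excluded from both
    numerator and denominator; ``include_missing`` instead counts them as
    discordant. Symmetric in its arguments.
    """
    shared = codes_a.index.intersection(codes_b.index)
    if len(shared) == 0:
        raise ValueError("marker panels are disjoint")
    a = codes_a.loc[shared]
    b = codes_b.loc[shared]
    both_called = (a != MISSING) & (b != MISSING)
    if include_missing:
        compared = pd.Series(True, index=shared)
        discordant = (a != b) & (compared)
    else:
        compared = both_called
        discordant = both_called & (a != b)
    n_compared = int(compared.sum())
    n_disc = int(discordant.sum())
    detail = pd.DataFrame(
        {
            "code_a": a,
            "code_b": b,
            "compared": compared,
            "discordant": discordant,
        }
    )
    pct = 100.0 * (n_compared - n_disc) / n_compared if n_compared else float("nan")
    return ConcordanceResult(
        n_markers=len(shared),
        n_compared=n_compared,
        n_discordant=n_disc,
        pct_concordant=pct,
        detail=detail,
    )


@dataclass
class P0Result:
    n_overlap: int
    n_mismatch: int
    p0: float
    normalized_p0: float | None
    low_confidence: bool


def p0_mismatch(
    calls_a: pd.Series,
    calls_b: pd.Series,
    baseline: float | None = None,
    min_overlap: int = 100,
) -> P0Result:
    """Pairwise mismatch rate of pseudohaploid calls over jointly called
    sites; low pooled P0 against an unrelated-pair baseline indicates the
    two libraries sample the same individual.

    ``baseline`` (expected mismatch rate for unrelated individuals) enables
    the normalized variant p0/baseline. Overlaps below ``min_overlap`` are
    flagged low-confidence.
    """
    shared = calls_a.index.intersection(calls_b.index)
    a = calls_a.loc[shared]
    b = calls_b.loc[shared]
    called = a.notna() & b.notna()
    n_overlap = int(called.sum())
    n_mismatch = int(((a != b) & called).sum())
    p0 = n_mismatch / n_overlap if n_overlap else float("nan")
    return P0Result(
        n_overlap=n_overlap,
        n_mismatch=n_mismatch,
        p0=p0,
        normalized_p0=(p0 / baseline) if baseline else None,
        low_confidence=n_overlap < min_overlap,
    )
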