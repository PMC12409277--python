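"""Taxonomic-report screening: parse KrakenUniq-dialect reports, score each
taxon with the E-score dispersal statistic, and apply the candidate-selection
and abundance filters used to pick reference genomes for competitive mapping.

The E-score rewards classification hits that are dispersed along a genome
over clonal, localised stacks of reads: with ``u`` unique k-mers observed
from ``r`` reads at genome k-mer coverage ``c``, the default strategy is

    E = (u / r) / c

Higher values indicate hits spread across the reference and hence a more
credible taxon call; the conventional retention threshold is E >= 7. The
formula is pluggable (``escore_strategy``) so alternative published
algebras can be swapped in without touching any filter logic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd

REPORT_COLUMNS = ["%", "reads", "taxReads", "kmers", "dup", "cov", "taxID", "rank", "taxName"]

_NUMERIC = {"%": float, "reads": int, "taxReads": int, "kmers": int, "dup": float, "cov": float, "taxID": int}

EScoreStrategy = Callable[[float, float, float], float]


def default_escore(kmers: float, reads: float, cov: float) -> float:
    return (kmers / reads) / cov


def kmers_per_read_escore(kmers: float, reads: float, cov: float) -> float:
    """Dispersal statistic that ignores coverage: unique k-mers per read.

    When a report's ``cov`` column is exactly unique k-mers over genome
    k-mers, the default algebra cancels to genome_kmers/reads and loses all
    dispersal information; this strategy keeps it (clonal read stacks
    re-observe the same k-mers and score near 1, dispersed reads score near
    the per-read k-mer yield).
    """
    return kmers / reads


def parse_report(path: str | Path) -> pd.DataFrame:
    """Parse a KrakenUniq-style report TSV, reconstructing the hierarchy.

    Taxon depth is encoded by two-space indentation of ``taxName``; each
    row's parent is the nearest preceding row at a shallower depth. Adds
    ``depth``, ``name`` (dedented) and ``parent_taxid`` (-1 at the root).
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in REPORT_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"report missing column(s): {', '.join(missing)}")
        idx = {c: header.index(c) for c in REPORT_COLUMNS}
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            row = {}
            for col in REPORT_COLUMNS:
                raw = fields[idx[col]]
                caster = _NUMERIC.get(col)
                if caster is not None:
                    try:
                        row[col] = caster(float(raw)) if caster is int else caster(raw)
                    except ValueError:
                        raise ValueError(
                            f"non-numeric value {raw!r} in column {col} at line {lineno}"
                        ) from None
                else:
                    row[col] = raw
            rows.append(row)
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    depths, names, parents = [], [], []
    stack: list[tuple[int, int]] = []  # (depth, taxID)
    for _, row in df.iterrows():
        name = row["taxName"]
        depth = (len(name) - len(name.lstrip(" "))) // 2
        while stack and stack[-1][0] >= depth:
            stack.pop()
        parents.append(stack[-1][1] if stack else -1)
        stack.append((depth, row["taxID"]))
        depths.append(depth)
        names.append(name.strip())
    df["depth"] = depths
    df["name"] = names
    df["parent_taxid"] = parents
    return df


def write_report(df: pd.DataFrame, path: str | Path) -> None:
    df[REPORT_COLUMNS].to_csv(path, sep="\t", index=False)


def escore(
    row: pd.Series | dict, strategy: EScoreStrategy = default_escore
) -> float:
    """E-score of one report row; NaN (unevaluable) when reads or cov is 0."""
    reads, cov, kmers = float(row["reads"]), float(row["cov"]), float(row["kmers"])
    if reads <= 0 or cov <= 0:
        return float("nan")
    return strategy(kmers, reads, cov)


def add_escore(df: pd.DataFrame, strategy: EScoreStrategy = default_escore) -> pd.DataFrame:
    out = df.copy()
    out["escore"] = [escore(row, strategy) for _, row in df.iterrows()]
    return out


def filter_rows(
    df: pd.DataFrame,
    min_escore: float = 7.0,
    min_reads: int = 10,
    min_rel_abundance: float = 0.0002,
) -> pd.DataFrame:
    """Retain rows with escore >= min_escore (inclusive), reads >= min_reads,
    and relative abundance >= min_rel_abundance. Unevaluable (NaN) E-scores
    never pass silently."""
    if "escore" not in df.columns:
        raise ValueError("compute escore first (add_escore)")
    total = df["reads"].sum()
    rel = df["reads"] / total if total else df["reads"] * 0.0
    mask = (
        df["escore"].notna()
        & (df["escore"] >= min_escore)
        & (df["reads"] >= min_reads)
        & (rel >= min_rel_abundance)
    )
    return df[mask].copy()


@dataclass
class CandidateSet:
    """Species retained per genus for competitive mapping, plus diagnostics."""

    candidates: pd.DataFrame  # genus, name, taxID, reads, mito_hits, escore
    genus_mito_hits: dict[str, int]
    unplaced: pd.DataFrame


def select_candidates(
    df: pd.DataFrame,
    min_genus_mito_hits: int = 4,
    min_escore: float = 7.0,
) -> CandidateSet:
    """Select species whose genus has more than three mitochondrial read hits
    and whose own E-score passes the threshold.

    ``df`` must be species rows from a mitochondrial/plastid-database screen
    with ``genus`` and ``escore`` columns; read counts against those entries
    are the "mitochondrial hits". Rows without a genus go to an unplaced
    bucket and are reported, never silently dropped.
    """
    if "escore" not in df.columns:
        raise ValueError("compute escore first (add_escore)")
    has_genus = df["genus"].notna() & (df["genus"] != "")
    unplaced = df[~has_genus].copy()
    placed = df[has_genus]
    mito_hits = placed.groupby("genus")["reads"].sum().to_dict()
    keep_genera = {g for g, n in mito_hits.items() if n >= min_genus_mito_hits}
    cand = placed[
        placed["genus"].isin(keep_genera)
        & placed["escore"].notna()
        & (placed["escore"] >= min_escore)
    ].copy()
    cand["mito_hits"] = cand["genus"].map(mito_hits)
    return CandidateSet(candidates=cand, genus_mito_hits=mito_hits, unplaced=unplaced)


def merge_normalize(
    reports: dict[str, pd.DataFrame],
    target: str,
    min_reads_ref: int = 200,
    min_reads_target: int = 50,
    min_rel: float = 0.0002,
) -> pd.DataFrame:
    """Merge per-sample species reports into a joint relative-abundance table.

    A species survives if it has at least ``min_reads_ref`` reads in every
    reference sample, at least ``min_reads_target`` reads in the target
    sample, and at least ``min_rel`` relative abundance in the pooled
    dataset. Retained counts are then normalised per sample by library size
    (each sample's retained abundances sum to 1).
    """
    if len(reports) < 2:
        raise ValueError("need the target plus at least one reference report")
    counts = pd.DataFrame(
        {name: df.set_index("name")["reads"] for name, df in reports.items()}
    ).fillna(0.0)
    ref_cols = [c for c in counts.columns if c != target]
    pooled = counts.sum(axis=1)
    rel = pooled / pooled.sum() if pooled.sum() else pooled
    mask = (
        (counts[ref_cols] >= min_reads_ref).all(axis=1)
        & (counts[target] >= min_reads_target)
        & (rel >= min_rel)
    )
    kept = counts[mask]
    if kept.empty:
        import warnings

        warnings.warn("no species survive the merge filters", stacklevel=2)
        return kept
    return kept / kept.sum(axis=0)
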