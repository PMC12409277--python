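"""Peptide-spectrum-match filtering and species-diagnostic peptide
resolution against a multi-species protein database.

Workflow: aggregate PSMs per peptide and keep confident evidence (score at
or below 0.01, at least two PSMs); match retained peptides as exact
substrings of database proteins, treating isoleucine and leucine as
equivalent by default (isobaric, indistinguishable by mass); a peptide
found in exactly one species' proteome is species-diagnostic, and the
residues at which the other species' homolog differs are reported.
Protein-level evidence requires at least two unique peptides, with a
"partial protein" label at >= 5% residue coverage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

_MOD_PAREN = re.compile(r"\(([^)]*)\)")


def _normalize_il(s: str) -> str:
    return s.replace("I", "L")


def strip_modifications(peptide: str) -> tuple[str, list[tuple[int, str]]]:
    """Split a peptide string with parenthesised modifications into the bare
    sequence and a list of (0-based residue position, modification) pairs."""
    mods: list[tuple[int, str]] = []
    out = []
    i = 0
    raw = peptide
    while i < len(raw):
        ch = raw[i]
        if ch == "(":
            close = raw.index(")", i)
            mods.append((len(out) - 1, raw[i + 1 : close]))
            i = close + 1
        else:
            out.append(ch)
            i += 1
    return "".join(out), mods


@dataclass
class PeptideEvidence:
    peptide: str
    psm_count: int
    best_score: float
    spectra: list[str]


def filter_psms(
    records: pd.DataFrame, max_score: float = 0.01, min_psms: int = 2
) -> dict[str, PeptideEvidence]:
    """Aggregate PSMs by (modification-stripped) peptide and keep peptides
    whose best score is <= max_score with >= min_psms spectra (both
    inclusive). Malformed peptide strings are rejected with the offending
    row index."""
    agg: dict[str, PeptideEvidence] = {}
    for idx, rec in records.iterrows():
        bare, _ = strip_modifications(str(rec["peptide"]))
        if not bare or set(bare) - VALID_AA:
            raise ValueError(f"malformed peptide {rec['peptide']!r} at row {idx}")
        ev = agg.get(bare)
        score = float(rec["score"])
        if ev is None:
            agg[bare] = PeptideEvidence(bare, 1, score, [str(rec["spectrum_id"])])
        else:
            ev.psm_count += 1
            ev.best_score = min(ev.best_score, score)
            ev.spectra.append(str(rec["spectrum_id"]))
    return {
        pep: ev
        for pep, ev in agg.items()
        if ev.best_score <= max_score and ev.psm_count >= min_psms
    }


@dataclass
class PeptideMatch:
    peptide: str
    species: set[str]
    proteins: dict[str, list[int]]  # accession -> 0-based match start positions
    diagnostic: bool
    diagnostic_residues: list[tuple[str, int]]  # (accession, protein position)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, start = [], 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def match_peptides(
    peptides: list[str],
    db: dict[str, tuple[str, str]],
    il_equivalent: bool = True,
) -> dict[str, PeptideMatch]:
    """Exact-substring search of each peptide against every database protein.

    ``db`` maps accession to (species, sequence). With ``il_equivalent`` the
    search treats I and L as one residue class. A peptide is diagnostic when
    its matched species set is a singleton; for those, the reported
    diagnostic residues are the positions inside the matched span where a
    same-length window of any other species' protein differs — i.e. the
    residues that make the peptide species-specific.
    """
    if not db:
        raise ValueError("empty protein database")
    norm_db = {
        acc: (sp, _normalize_il(seq) if il_equivalent else seq)
        for acc, (sp, seq) in db.items()
    }
    out: dict[str, PeptideMatch] = {}
    for pep in peptides:
        query = _normalize_il(pep) if il_equivalent else pep
        proteins: dict[str, list[int]] = {}
        species: set[str] = set()
        for acc, (sp, seq) in norm_db.items():
            hits = _find_all(seq, query)
            if hits:
                proteins[acc] = hits
                species.add(sp)
        diagnostic = len(species) == 1
        residues: list[tuple[str, int]] = []
        if diagnostic and len({sp for sp, _ in db.values()}) > 1:
            matched_sp = next(iter(species))
            for acc, starts in proteins.items():
                for start in starts:
                    for other_acc, (other_sp, other_seq) in norm_db.items():
                        if other_sp == matched_sp:
                            continue
                        window = other_seq[start : start + len(query)]
                        if len(window) != len(query):
                            continue
                        diffs = [
                            start + i
                            for i, (a, b) in enumerate(zip(query, window))
                            if a != b
                        ]
                        # homologous window: nearly identical apart from the
                        # diagnostic residue(s)
                        if 0 < len(diffs) <= max(2, len(query) // 5):
                            residues.extend((other_acc, d) for d in diffs)
        out[pep] = PeptideMatch(
            peptide=pep,
            species=species,
            proteins=proteins,
            diagnostic=diagnostic,
            diagnostic_residues=sorted(set(residues)),
        )
    return out


@dataclass
class ProteinEvidence:
    accession: str
    species: str
    unique_peptides: set[str]
    coverage: float
    partial: bool  # coverage >= the partial-protein label threshold


def protein_evidence(
    matches: dict[str, PeptideMatch],
    db: dict[str, tuple[str, str]],
    min_unique_peptides: int = 2,
    partial_coverage: float = 0.05,
) -> dict[str, ProteinEvidence]:
    """Aggregate peptide matches to protein level.

    Coverage is the fraction of protein residues covered by the union of
    matched peptide intervals. Proteins with fewer than
    ``min_unique_peptides`` unique peptides are dropped; those at coverage
    >= ``partial_coverage`` carry the partial-protein label.
    """
    per_protein: dict[str, dict[str, list[int]]] = {}
    for pep, match in matches.items():
        for acc, starts in match.proteins.items():
            per_protein.setdefault(acc, {})[pep] = starts
    out: dict[str, ProteinEvidence] = {}
    for acc, peps in per_protein.items():
        if len(peps) < min_unique_peptides:
            continue
        sp, seq = db[acc]
        covered = [False] * len(seq)
        for pep, starts in peps.items():
            for start in starts:
                for i in range(start, min(start + len(pep), len(seq))):
                    covered[i] = True
        cov = sum(covered) / len(seq)
        out[acc] = ProteinEvidence(
            accession=acc,
            species=sp,
            unique_peptides=set(peps),
            coverage=cov,
            partial=cov >= partial_coverage,
        )
    return out


def blank_subtract(
    evidence: dict[str, PeptideEvidence],
    blank_evidence: dict[str, PeptideEvidence] | None = None,
    contaminant_matches: dict[str, PeptideMatch] | None = None,
) -> tuple[dict[str, PeptideEvidence], dict[str, int]]:
    """Remove peptides seen in the extraction blank or matching a
    contaminant database; removals tallied by cause (blank checked first)."""
    removed = {"blank": 0, "contaminant": 0}
    blank_peps = set(blank_evidence or {})
    kept: dict[str, PeptideEvidence] = {}
    for pep, ev in evidence.items():
        if pep in blank_peps:
            removed["blank"] += 1
        elif contaminant_matches and contaminant_matches.get(pep) and contaminant_matches[pep].proteins:
            removed["contaminant"] += 1
        else:
            kept[pep] = ev
    return kept, removed


def read_protein_fasta(path: str | Path) -> dict[str, tuple[str, str]]:
    """Protein FASTA with a ``species=`` key in each header."""
    from .core import read_fasta

    db: dict[str, tuple[str, str]] = {}
    for header, seq in read_fasta(path).items():
        parts = header.split()
        acc = parts[0]
        species = "unknown"
        for p in parts[1:]:
            if p.startswith("species="):
                species = p[len("species=") :].replace("_", " ")
        db[acc] = (species, seq)
    return db


def ptm_proportions(records: pd.DataFrame) -> pd.Series:
    """Proportion of each modification type relative to total residues
    across all (unfiltered) PSM peptides."""
    total_aa = 0
    counts: dict[str, int] = {}
    for _, rec in records.iterrows():
        bare, mods = strip_modifications(str(rec["peptide"]))
        total_aa += len(bare)
        for _, mod in mods:
            counts[mod] = counts.get(mod, 0) + 1
    return pd.Series(
        {mod: n / total_aa for mod, n in counts.items()} if total_aa else {},
        dtype=float,
    )
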