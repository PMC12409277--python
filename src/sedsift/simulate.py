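"""Synthetic-data generation for every pipeline input, with known truth.

The generator emulates shotgun sequencing of a sediment-derived DNA extract:
a mixture of taxa with lognormal fragment lengths, position-decaying terminal
cytosine deamination (C>T at the 5' end, symmetric G>A at the 3' end for
double-stranded libraries), uniform sequencing error, and an admixed
undamaged modern contaminant. It also produces sex-chromosome read counts,
allele-depth pileups with a known contamination fraction, k-mer
classification reports, and peptide-spectrum-match tables against a
two-species protein database — each paired with a truth table so parameter
recovery can be asserted downstream.

Randomness is organised as named sub-streams spawned from the master seed,
so toggling one model (e.g. sequencing error) never perturbs another
(e.g. fragmentation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AlignmentRecord, ReadRecord, make_md_tag, revcomp

BASES = "ACGT"

_ROLES = {"autosome", "chrX", "chrY", "mitochondrion", "plastid"}


@dataclass(frozen=True)
class ReferenceSeq:
    """One reference sequence of a taxon with its chromosomal role."""

    seq_id: str
    role: str
    seq: str

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise ValueError(f"unknown reference role {self.role!r}")
        if not self.seq or set(self.seq) - set(BASES):
            raise ValueError(f"reference {self.seq_id} must be non-empty over ACGT")


@dataclass
class TaxonSpec:
    """A mixture component: taxon identity, references, and read fraction."""

    taxon_id: str
    name: str
    genus: str
    abundance: float
    references: list[ReferenceSeq]

    def reference(self, seq_id: str) -> ReferenceSeq:
        for ref in self.references:
            if ref.seq_id == seq_id:
                return ref
        raise KeyError(seq_id)


@dataclass
class DamageModel:
    """Geometric-decay terminal deamination model.

    The per-position rate is ``floor + (peak - floor) * decay**(i-1)`` for
    1-based distance ``i`` from the fragment end: C>T counted from the 5'
    end and, for double-stranded library preparation, G>A counted from the
    3' end with the same magnitudes.
    """

    delta5: float = 0.2
    decay: float = 0.6
    delta_base: float = 0.01
    double_stranded: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta_base <= self.delta5 <= 1.0):
            raise ValueError("require 0 <= delta_base <= delta5 <= 1")
        if not (0.0 < self.decay <= 1.0):
            raise ValueError("decay must lie in (0, 1]")

    def rate(self, i: int) -> float:
        """Deamination probability at 1-based distance ``i`` from the end."""
        return self.delta_base + (self.delta5 - self.delta_base) * self.decay ** (i - 1)


@dataclass
class FragmentModel:
    """Truncated lognormal fragment-length model for degraded DNA."""

    log_mean: float = math.log(55.0)
    log_sd: float = 0.35
    min_len: int = 30
    max_len: int = 150

    def __post_init__(self) -> None:
        if self.min_len < 20:
            raise ValueError("min_len must be >= 20")
        if self.max_len < self.min_len:
            raise ValueError("max_len < min_len")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        draws = rng.lognormal(self.log_mean, self.log_sd, size=n)
        return np.clip(np.rint(draws), self.min_len, self.max_len).astype(int)


@dataclass
class SimConfig:
    """Run-level knobs: read count, error rate, contaminant admixture, seed."""

    seed: int
    n_reads: int
    error_rate: float = 0.001
    contamination_fraction: float = 0.0
    quality_constant: int = 37

    def __post_init__(self) -> None:
        if not (0.0 <= self.contamination_fraction <= 1.0):
            raise ValueError("contamination_fraction must lie in [0, 1]")


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _apply_damage(
    frag: str, dmg: DamageModel, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Deaminate a fragment in read orientation; return sequence + positions."""
    bases = list(frag)
    n = len(bases)
    hit: list[int] = []
    for i, b in enumerate(bases):
        if b == "C":
            if rng.random() < dmg.rate(i + 1):
                bases[i] = "T"
                hit.append(i)
        elif b == "G" and dmg.double_stranded:
            if rng.random() < dmg.rate(n - i):
                bases[i] = "A"
                hit.append(i)
    return "".join(bases), hit


def _apply_error(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    bases = list(seq)
    for i, b in enumerate(bases):
        if rng.random() < error_rate:
            alternatives = [x for x in BASES if x != b]
            bases[i] = alternatives[rng.integers(3)]
    return "".join(bases)


def simulate_metagenome(
    mixture: list[TaxonSpec],
    frag: FragmentModel,
    dmg: DamageModel,
    cfg: SimConfig,
    contaminant: TaxonSpec | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame, list[AlignmentRecord]]:
    """Simulate a taxon mixture and return (reads, truth table, alignments).

    Read counts per taxon are multinomial in the declared abundances;
    contaminant reads (an undamaged modern admixture) are drawn first as a
    binomial fraction of the total. Truth alignments are exact placements
    with MD/NM computed against the source reference, so the damage and
    error a read carries is exactly the mismatch set of its alignment.
    """
    if not mixture:
        raise ValueError("mixture must be non-empty")
    total_ab = sum(t.abundance for t in mixture)
    if abs(total_ab - 1.0) > 1e-9:
        raise ValueError(f"mixture abundances sum to {total_ab}, expected 1")
    if cfg.contamination_fraction > 0 and contaminant is None:
        raise ValueError("contamination_fraction > 0 requires a contaminant source")
    for taxon in list(mixture) + ([contaminant] if contaminant else []):
        for ref in taxon.references:
            if len(ref.seq) <= frag.max_len:
                raise ValueError(
                    f"reference {ref.seq_id} of {taxon.taxon_id} is shorter than "
                    f"the maximum fragment length {frag.max_len}"
                )

    rng = _streams(
        cfg.seed, ["taxon", "fragment", "damage", "error", "contamination"]
    )

    n_contam = (
        rng["contamination"].binomial(cfg.n_reads, cfg.contamination_fraction)
        if contaminant is not None
        else 0
    )
    n_endo = cfg.n_reads - n_contam
    counts = rng["taxon"].multinomial(n_endo, [t.abundance for t in mixture])

    assignments: list[tuple[TaxonSpec, bool]] = []
    for taxon, k in zip(mixture, counts):
        assignments.extend([(taxon, False)] * int(k))
    assignments.extend([(contaminant, True)] * n_contam)

    lengths = frag.sample(rng["fragment"], len(assignments))

    reads: list[ReadRecord] = []
    alignments: list[AlignmentRecord] = []
    truth_rows: list[dict] = []
    for idx, ((taxon, is_contam), length) in enumerate(zip(assignments, lengths)):
        ref = taxon.references[
            rng["fragment"].integers(len(taxon.references))
            if len(taxon.references) > 1
            else 0
        ]
        start = int(rng["fragment"].integers(len(ref.seq) - length + 1))
        end = start + int(length)
        strand = "+" if rng["fragment"].random() < 0.5 else "-"
        frag_seq = ref.seq[start:end]
        if strand == "-":
            frag_seq = revcomp(frag_seq)

        if is_contam:
            damaged, dmg_pos = frag_seq, []
        else:
            damaged, dmg_pos = _apply_damage(frag_seq, dmg, rng["damage"])
        final = _apply_error(damaged, cfg.error_rate, rng["error"])

        read_id = f"read{idx:07d}"
        quals = [cfg.quality_constant] * len(final)
        reads.append(ReadRecord(read_id, final, quals))

        ref_oriented = revcomp(final) if strand == "-" else final
        md, nm = make_md_tag(ref_oriented, ref.seq[start:end])
        alignments.append(
            AlignmentRecord(
                read_id=read_id,
                ref_id=ref.seq_id,
                pos=start,
                strand=strand,
                cigar=f"{len(final)}M",
                nm=nm,
                mapq=60,
                seq=ref_oriented,
                md=md,
            )
        )
        truth_rows.append(
            {
                "read_id": read_id,
                "taxon_id": taxon.taxon_id,
                "seq_id": ref.seq_id,
                "start": start,
                "end": end,
                "strand": strand,
                "damaged_positions": ",".join(map(str, dmg_pos)),
                "is_contaminant": is_contam,
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "taxon_id",
            "seq_id",
            "start",
            "end",
            "strand",
            "damaged_positions",
            "is_contaminant",
        ],
    )
    return reads, truth, alignments


def mutate_reference(seq: str, identity: float, seed: int) -> str:
    """Derive a homologous reference at the given sequence identity."""
    rng = np.random.default_rng(seed)
    bases = list(seq)
    for i, b in enumerate(bases):
        if rng.random() > identity:
            alternatives = [x for x in BASES if x != b]
            bases[i] = alternatives[rng.integers(3)]
    return "".join(bases)


def competitive_alignments(
    reads: list[ReadRecord],
    truth: pd.DataFrame,
    references: dict[str, str],
    mapq: int = 60,
) -> list[AlignmentRecord]:
    """Place each read at its true coordinates on every candidate reference.

    The candidates must be coordinate-matched homologs (e.g. produced by
    :func:`mutate_reference`), so the true placement is also the correct
    placement on each competitor; only the mismatch count differs.
    """
    by_id = truth.set_index("read_id")
    out: list[AlignmentRecord] = []
    for read in reads:
        row = by_id.loc[read.read_id]
        ref_oriented = revcomp(read.seq) if row["strand"] == "-" else read.seq
        for ref_name, ref_seq in references.items():
            ref_slice = ref_seq[row["start"] : row["end"]]
            md, nm = make_md_tag(ref_oriented, ref_slice)
            out.append(
                AlignmentRecord(
                    read_id=read.read_id,
                    ref_id=ref_name,
                    pos=int(row["start"]),
                    strand=row["strand"],
                    cigar=f"{len(read.seq)}M",
                    nm=nm,
                    mapq=mapq,
                    seq=ref_oriented,
                    md=md,
                )
            )
    return out


def simulate_sex_readset(
    sex: str,
    n_reads: int,
    layout: dict[str, tuple[str, int]],
    seed: int,
    y_noise: float = 0.0,
) -> dict[str, int]:
    """Distribute aligned reads over chromosomes according to genetic sex.

    ``layout`` maps chromosome name to (role, length). Expected reads per
    chromosome are proportional to copy number x length: autosomes carry 2
    copies; XY carries one X and one Y (so X and Y each sit at half the
    autosomal per-bp rate); XX carries two X and zero Y apart from a
    mis-mapping noise floor expressed as an effective Y copy number.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if sex not in {"XX", "XY"}:
        raise ValueError("sex must be 'XX' or 'XY'")
    roles = {name: role for name, (role, _) in layout.items()}
    if "chrX" not in roles.values():
        raise ValueError("layout must include a chrX reference")

    copies: dict[str, float] = {}
    for name, (role, length) in layout.items():
        if role == "chrX":
            copies[name] = 2.0 if sex == "XX" else 1.0
        elif role == "chrY":
            copies[name] = y_noise if sex == "XX" else 1.0
        else:
            copies[name] = 2.0
    weights = np.array(
        [copies[name] * layout[name][1] for name in layout], dtype=float
    )
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n_reads, weights)
    return {name: int(c) for name, c in zip(layout, counts)}


def simulate_pileup(
    sites: pd.DataFrame,
    mean_depth: float,
    contamination: float,
    seed: int,
    error_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate allele-depth pileups over haplotype-diagnostic sites.

    ``sites`` needs columns chrom, pos, ref, endo_allele, contam_allele,
    diagnostic (bool). Site depth is Poisson(mean_depth); each covering read
    comes from the contaminant haplotype with probability ``contamination``
    and otherwise from the endogenous one, then suffers a uniform base error
    at ``error_rate``. Returns (pileup table, per-site truth).
    """
    if not (0.0 <= contamination <= 1.0):
        raise ValueError("contamination must lie in [0, 1]")
    diag = sites[sites["diagnostic"]]
    if diag.empty:
        raise ValueError("no diagnostic sites supplied")
    bad = diag[diag["endo_allele"] == diag["contam_allele"]]
    if not bad.empty:
        raise ValueError(
            "diagnostic sites must differ between endogenous and contaminant "
            f"haplotypes (first offender: pos {int(bad.iloc[0]['pos'])})"
        )

    rng = np.random.default_rng(seed)
    pile_rows, truth_rows = [], []
    for _, site in sites.iterrows():
        depth = int(rng.poisson(mean_depth))
        counts = {b: 0 for b in BASES}
        n_contam_reads = int(rng.binomial(depth, contamination))
        for base, n in (
            (site["contam_allele"], n_contam_reads),
            (site["endo_allele"], depth - n_contam_reads),
        ):
            if n == 0:
                continue
            n_err = int(rng.binomial(n, error_rate)) if error_rate > 0 else 0
            counts[base] += n - n_err
            if n_err:
                others = [x for x in BASES if x != base]
                for b, k in zip(others, rng.multinomial(n_err, [1 / 3] * 3)):
                    counts[b] += int(k)
        pile_rows.append(
            {
                "chrom": site["chrom"],
                "pos": int(site["pos"]),
                "ref": site["ref"],
                **counts,
                "N": 0,
            }
        )
        truth_rows.append(
            {
                "chrom": site["chrom"],
                "pos": int(site["pos"]),
                "depth": depth,
                "n_contaminant_reads": n_contam_reads,
                "diagnostic": bool(site["diagnostic"]),
            }
        )
    return pd.DataFrame(pile_rows), pd.DataFrame(truth_rows)


def synth_tax_report(
    truth: pd.DataFrame,
    mixture: list[TaxonSpec],
    k: int = 31,
    roles: set[str] | None = None,
    taxid_start: int = 1000,
) -> pd.DataFrame:
    """Build a k-mer classification report from simulation truth.

    Emulates the KrakenUniq report columns (%, reads, taxReads, kmers, dup,
    cov, taxID, rank, taxName) by counting the distinct reference k-mer
    start positions covered by each taxon's reads: ``kmers`` is the size of
    that set capped by the genome k-mer count, ``dup`` the mean observations
    per unique k-mer, ``cov`` the fraction of genome k-mers observed.
    Species rows are indented beneath genus rows as in the real format.
    ``roles`` restricts counting to references with those roles (e.g.
    {'mitochondrion'} for a mito-database screen).
    """
    if k < 21:
        raise ValueError("k must be >= 21")
    ref_info = {
        ref.seq_id: (taxon, ref)
        for taxon in mixture
        for ref in taxon.references
    }
    per_taxon: dict[str, dict] = {}
    for taxon in mixture:
        refs = [
            r
            for r in taxon.references
            if roles is None or r.role in roles
        ]
        genome_kmers = sum(max(len(r.seq) - k + 1, 0) for r in refs)
        per_taxon[taxon.taxon_id] = {
            "taxon": taxon,
            "kmer_positions": set(),
            "total_obs": 0,
            "reads": 0,
            "genome_kmers": genome_kmers,
        }
    for _, row in truth.iterrows():
        taxon, ref = ref_info[row["seq_id"]]
        if roles is not None and ref.role not in roles:
            continue
        acc = per_taxon[taxon.taxon_id]
        acc["reads"] += 1
        start, end = int(row["start"]), int(row["end"])
        for p in range(start, max(end - k + 1, start)):
            if end - start >= k:
                acc["kmer_positions"].add((row["seq_id"], p))
        acc["total_obs"] += max(end - start - k + 1, 0)

    total_reads = sum(a["reads"] for a in per_taxon.values())
    genera: dict[str, list[dict]] = {}
    taxid = taxid_start
    for acc in per_taxon.values():
        taxon = acc["taxon"]
        unique = min(len(acc["kmer_positions"]), acc["genome_kmers"])
        row = {
            "%": 100.0 * acc["reads"] / total_reads if total_reads else 0.0,
            "reads": acc["reads"],
            "taxReads": acc["reads"],
            "kmers": unique,
            "dup": acc["total_obs"] / unique if unique else 0.0,
            "cov": unique / acc["genome_kmers"] if acc["genome_kmers"] else 0.0,
            "taxID": 0,
            "rank": "species",
            "taxName": taxon.name,
            "genus": taxon.genus,
        }
        genera.setdefault(taxon.genus, []).append(row)

    out_rows = []
    for genus, species_rows in sorted(genera.items()):
        g_reads = sum(r["reads"] for r in species_rows)
        out_rows.append(
            {
                "%": 100.0 * g_reads / total_reads if total_reads else 0.0,
                "reads": g_reads,
                "taxReads": 0,
                "kmers": sum(r["kmers"] for r in species_rows),
                "dup": 0.0,
                "cov": 0.0,
                "taxID": taxid,
                "rank": "genus",
                "taxName": genus,
            }
        )
        taxid += 1
        for r in sorted(species_rows, key=lambda x: x["taxName"]):
            r = dict(r)
            r.pop("genus")
            r["taxID"] = taxid
            r["taxName"] = "  " + r["taxName"]  # one level beneath genus
            taxid += 1
            out_rows.append(r)
    return pd.DataFrame(
        out_rows,
        columns=["%", "reads", "taxReads", "kmers", "dup", "cov", "taxID", "rank", "taxName"],
    )


AA = "ACDEFGHIKLMNPQRSTVWY"


def make_two_species_protein_db(
    seed: int,
    species: tuple[str, str] = ("Rattus rattus", "Rattus norvegicus"),
    n_proteins: int = 3,
    length: int = 120,
    n_diagnostic: int = 1,
) -> tuple[dict[str, tuple[str, str]], dict[str, list[int]]]:
    """Random homologous protein pairs differing at single diagnostic residues.

    Returns (db, diagnostic_positions): ``db`` maps accession to
    (species, sequence); homolog pairs share a base accession with a
    species suffix, and differ exactly at the listed 0-based positions.
    """
    rng = np.random.default_rng(seed)
    db: dict[str, tuple[str, str]] = {}
    diag: dict[str, list[int]] = {}
    for p in range(n_proteins):
        base = "".join(AA[i] for i in rng.integers(len(AA), size=length))
        positions = sorted(
            int(x) for x in rng.choice(length, size=n_diagnostic, replace=False)
        )
        variant = list(base)
        for pos in positions:
            current = variant[pos]
            choices = [a for a in AA if a != current and a not in "IL"]
            variant[pos] = choices[rng.integers(len(choices))]
        acc = f"PROT{p:03d}"
        db[f"{acc}_A"] = (species[0], base)
        db[f"{acc}_B"] = (species[1], "".join(variant))
        diag[acc] = positions
    return db, diag


def synth_psm_table(
    db: dict[str, tuple[str, str]],
    diagnostic_positions: dict[str, list[int]],
    n_psms: int,
    seed: int,
    source_species: str | None = None,
    pep_len: tuple[int, int] = (9, 25),
    frac_diagnostic: float = 0.5,
    frac_high_score: float = 0.2,
) -> pd.DataFrame:
    """Emit a PSM table whose peptides are true substrings of one species.

    Peptides are drawn from the proteins of ``source_species`` (defaults to
    the first species in the database); a fraction spans a diagnostic
    position. Scores are small (confident) except a planted fraction above
    the conventional 0.01 cutoff. Truth columns record the source protein
    and whether the peptide covers a diagnostic residue.
    """
    rng = np.random.default_rng(seed)
    species_in_db = list(dict.fromkeys(sp for sp, _ in db.values()))
    if source_species is None:
        source_species = species_in_db[0]
    for base, positions in diagnostic_positions.items():
        seqs = [s for acc, (sp, s) in db.items() if acc.startswith(base)]
        for pos in positions:
            if len({s[pos] for s in seqs}) < 2:
                raise ValueError(
                    f"diagnostic position {pos} of {base} is identical in both species"
                )
    source_accs = [acc for acc, (sp, _) in db.items() if sp == source_species]
    rows = []
    for i in range(n_psms):
        acc = source_accs[rng.integers(len(source_accs))]
        _, prot = db[acc]
        base_acc = acc.rsplit("_", 1)[0]
        positions = diagnostic_positions.get(base_acc, [])
        length = int(rng.integers(pep_len[0], pep_len[1] + 1))
        want_diag = positions and rng.random() < frac_diagnostic
        if want_diag:
            pos = positions[rng.integers(len(positions))]
            lo = max(0, pos - length + 1)
            hi = min(pos, len(prot) - length)
            start = int(rng.integers(lo, hi + 1)) if hi >= lo else max(0, pos - length + 1)
        else:
            start = int(rng.integers(0, len(prot) - length + 1))
        peptide = prot[start : start + length]
        covers = any(start <= p < start + length for p in positions)
        score = (
            float(rng.uniform(0.011, 0.5))
            if rng.random() < frac_high_score
            else float(rng.uniform(1e-6, 0.01))
        )
        rows.append(
            {
                "spectrum_id": f"spec{i:05d}",
                "peptide": peptide,
                "modifications": "",
                "score": round(score, 6),
                "accessions": acc,
                "true_species": source_species,
                "covers_diagnostic": covers,
            }
        )
    return pd.DataFrame(rows)
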