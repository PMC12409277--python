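"""Per-sample biological inference: genetic sex (read-ratio and normalized
coverage estimators), mitochondrial contamination from allele depths,
a heterozygosity screen for the number of individuals behind a haploid
genome, and filtered consensus calling with N-masking.

The read-ratio sex classifier is the Ry statistic nY/(nX+nY) over reads
aligned to the sex chromosomes: below 0.016 calls female (XX), above 0.077
calls male (XY), values between are undetermined. The coverage estimator
compares Y and X coverage normalized by autosomal coverage: in a male X and
Y each sit at half the autosomal rate (Y/X near 1), in a female Y coverage
collapses toward 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

RY_FEMALE_MAX = 0.016
RY_MALE_MIN = 0.077

TRANSITIONS = {frozenset("CT"), frozenset("GA")}

BASES = ("A", "C", "G", "T")


@dataclass
class SexResult:
    nX: int | None
    nY: int | None
    ratio: float
    ci95: tuple[float, float] | None
    call: str  # 'XX' | 'XY' | 'undetermined'
    method: str  # 'read-ratio' | 'coverage-ratio'


def ry_sex(
    nX: int, nY: int, female_max: float = RY_FEMALE_MAX, male_min: float = RY_MALE_MIN
) -> SexResult:
    """Sex call from sex-chromosome read counts via Ry = nY/(nX+nY).

    Ry < female_max calls XX, Ry > male_min calls XY, in between is
    undetermined. The decision uses the point estimate; the normal 95% CI
    is reported for the user.
    """
    total = nX + nY
    if total <= 0:
        raise ValueError("nX + nY must be positive")
    ry = nY / total
    half = 1.96 * math.sqrt(ry * (1 - ry) / total)
    if ry < female_max:
        call = "XX"
    elif ry > male_min:
        call = "XY"
    else:
        call = "undetermined"
    return SexResult(
        nX=nX,
        nY=nY,
        ratio=ry,
        ci95=(max(ry - half, 0.0), min(ry + half, 1.0)),
        call=call,
        method="read-ratio",
    )


def coverage_sex(
    normX: float, normY: float, male_min: float = 0.75, female_max: float = 0.25
) -> SexResult:
    """Sex call from autosome-normalized X and Y coverage, r = normY/normX.

    A male's single X and Y each carry half the autosomal copy number so r
    is near 1; a female's Y coverage is near 0. Default decision bands are
    r >= 0.75 for XY and r <= 0.25 for XX.
    """
    if normX <= 0:
        raise ValueError("normalized X coverage must be positive")
    r = normY / normX
    if r >= male_min:
        call = "XY"
    elif r <= female_max:
        call = "XX"
    else:
        call = "undetermined"
    return SexResult(nX=None, nY=None, ratio=r, ci95=None, call=call, method="coverage-ratio")


@dataclass
class ContamEstimate:
    n_sites_used: int
    n_sites_skipped: int
    per_site: pd.DataFrame  # chrom, pos, majority, minority, fraction
    estimate: float
    ci95: tuple[float, float]


def contamination_ratio(
    pileup: pd.DataFrame, diagnostic_sites: list[tuple[str, int]]
) -> ContamEstimate:
    """Contamination as the pooled minority/(majority+minority) allele-depth
    ratio over annotated diagnostic sites.

    Sites absent from the pileup (or with zero depth) are skipped and
    counted. The 95% CI is the normal approximation on the pooled binomial.
    """
    if not diagnostic_sites:
        raise ValueError("no diagnostic sites supplied")
    indexed = pileup.set_index(["chrom", "pos"])
    rows = []
    skipped = 0
    maj_total = 0
    min_total = 0
    for chrom, pos in diagnostic_sites:
        try:
            site = indexed.loc[(chrom, pos)]
        except KeyError:
            skipped += 1
            continue
        counts = sorted((int(site[b]) for b in BASES), reverse=True)
        majority, minority = counts[0], counts[1]
        if majority == 0:
            skipped += 1
            continue
        maj_total += majority
        min_total += minority
        rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "majority": majority,
                "minority": minority,
                "fraction": minority / (majority + minority),
            }
        )
    per_site = pd.DataFrame(rows, columns=["chrom", "pos", "majority", "minority", "fraction"])
    n = maj_total + min_total
    c = min_total / n if n else 0.0
    half = 1.96 * math.sqrt(c * (1 - c) / n) if n else 0.0
    return ContamEstimate(
        n_sites_used=len(rows),
        n_sites_skipped=skipped,
        per_site=per_site,
        estimate=c,
        ci95=(max(c - half, 0.0), min(c + half, 1.0)),
    )


@dataclass
class HetScreen:
    n_sites_considered: int
    n_transversion_het: int
    het_rate: float
    verdict: str  # 'single-individual-consistent' | 'multiple-or-contaminated'


def het_screen(
    pileup: pd.DataFrame, min_depth: int = 5, min_minor_frac: float = 0.1
) -> HetScreen:
    """Count transversion-heterozygous sites on a haploid reference.

    A site is heterozygous evidence when two alleles each reach
    ``min_minor_frac`` of a depth >= ``min_depth``; transition pairs (C<->T,
    G<->A) are discarded as candidate post-mortem deamination artefacts and
    never counted. Zero transversion-het sites is consistent with a single
    individual.
    """
    if pileup.empty:
        raise ValueError("empty pileup")
    considered = 0
    transversion_het = 0
    for _, site in pileup.iterrows():
        counts = {b: int(site[b]) for b in BASES}
        depth = sum(counts.values())
        if depth < min_depth:
            continue
        alleles = sorted(
            (b for b in BASES if counts[b] > 0), key=lambda b: -counts[b]
        )
        if len(alleles) != 2:
            if len(alleles) > 2:
                # keep top two; extra alleles at trace level are noise
                alleles = alleles[:2]
            else:
                continue
        a, b = alleles
        if counts[b] / depth < min_minor_frac:
            continue
        considered += 1
        if frozenset((a, b)) not in TRANSITIONS:
            transversion_het += 1
    return HetScreen(
        n_sites_considered=considered,
        n_transversion_het=transversion_het,
        het_rate=transversion_het / considered if considered else 0.0,
        verdict=(
            "single-individual-consistent"
            if transversion_het == 0
            else "multiple-or-contaminated"
        ),
    )


@dataclass
class ConsensusResult:
    sequence: str
    n_sites: int
    n_emitted: int
    n_masked_depth: int
    n_masked_gq: int
    n_masked_allele_ratio: int


def genotype_quality_from_depths(majority: int, minority: int, error: float = 0.01) -> float:
    """Phred-scaled confidence that the majority allele is the true haploid
    allele, under a symmetric per-read error model.

    This is a convenience for pileup-only input where no caller GQ exists;
    it is a simple likelihood-ratio score, not a caller reimplementation.
    """
    ll_maj = majority * math.log10(1 - error) + minority * math.log10(error / 3)
    ll_min = minority * math.log10(1 - error) + majority * math.log10(error / 3)
    return 10.0 * (ll_maj - ll_min)


def consensus_call(
    sites: pd.DataFrame,
    min_depth: int = 5,
    min_gq: float = 20.0,
    homozygous_recode_ratio: float = 1.0 / 9.0,
) -> ConsensusResult:
    """Filtered haploid consensus with N-masking.

    ``sites`` needs columns pos (1-based, contiguous ordering assumed),
    depth, gq, majority_allele, majority_depth, minority_depth. A site
    emits its majority allele when depth >= min_depth, gq >= min_gq, and
    either it is effectively homozygous or its minority:majority allele-depth
    ratio is <= the recode ratio (default 1/9), in which case it is recoded
    homozygous for the majority allele; everything else is masked as N.
    """
    bases = []
    n_depth = n_gq = n_ratio = n_emitted = 0
    for _, site in sites.iterrows():
        if site["depth"] < min_depth:
            bases.append("N")
            n_depth += 1
            continue
        if site["gq"] < min_gq:
            bases.append("N")
            n_gq += 1
            continue
        majority = int(site["majority_depth"])
        minority = int(site["minority_depth"])
        if minority > 0 and majority > 0 and minority / majority > homozygous_recode_ratio:
            bases.append("N")
            n_ratio += 1
            continue
        bases.append(site["majority_allele"])
        n_emitted += 1
    return ConsensusResult(
        sequence="".join(bases),
        n_sites=len(sites),
        n_emitted=n_emitted,
        n_masked_depth=n_depth,
        n_masked_gq=n_gq,
        n_masked_allele_ratio=n_ratio,
    )
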