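"""Tests of the synthetic-data generator against independent oracles:
exact-substring identity without damage, byte determinism, multinomial and
binomial count recovery, k-mer set logic, and truth-table conservation."""

import math

import numpy as np
import pandas as pd
import pytest

from sedsift.core import revcomp, write_fastq
from sedsift.simulate import (
    DamageModel,
    FragmentModel,
    ReferenceSeq,
    SimConfig,
    TaxonSpec,
    make_two_species_protein_db,
    simulate_metagenome,
    simulate_pileup,
    simulate_sex_readset,
    synth_psm_table,
    synth_tax_report,
)
from conftest import make_taxon


class TestSimulateMetagenome:
    def test_zero_damage_reads_are_exact_substrings(self, two_taxon_mixture):
        cfg = SimConfig(seed=3, n_reads=300, error_rate=0.0)
        dmg = DamageModel(delta5=0.0, decay=0.5, delta_base=0.0)
        reads, truth, alns = simulate_metagenome(
            two_taxon_mixture, FragmentModel(), dmg, cfg
        )
        refs = {
            r.seq_id: r.seq for t in two_taxon_mixture for r in t.references
        }
        for read, (_, row) in zip(reads, truth.iterrows()):
            frag = refs[row["seq_id"]][row["start"] : row["end"]]
            if row["strand"] == "-":
                frag = revcomp(frag)
            assert read.seq == frag
            assert row["damaged_positions"] == ""

    def test_determinism_byte_identical(self, two_taxon_mixture, tmp_path):
        cfg = SimConfig(seed=42, n_reads=150)
        outputs = []
        for run in ("a", "b"):
            reads, truth, _ = simulate_metagenome(
                two_taxon_mixture, FragmentModel(), DamageModel(), cfg
            )
            fq = tmp_path / f"{run}.fastq"
            write_fastq(reads, fq)
            outputs.append((fq.read_bytes(), truth.to_csv()))
        assert outputs[0] == outputs[1]

    def test_taxon_counts_multinomial(self, two_taxon_mixture):
        n = 10_000
        cfg = SimConfig(seed=5, n_reads=n)
        _, truth, _ = simulate_metagenome(
            two_taxon_mixture, FragmentModel(), DamageModel(), cfg
        )
        counts = truth["taxon_id"].value_counts()
        for taxon, p in (("speciesA", 0.7), ("speciesB", 0.3)):
            tol = 3 * math.sqrt(n * p * (1 - p))
            assert abs(counts[taxon] - n * p) < tol

    def test_damage_only_at_reference_c_or_g(self, damaged_simulation):
        reads, truth, _ = damaged_simulation
        refs_by_read = truth.set_index("read_id")
        mixture_refs = {}
        for _, row in truth.iterrows():
            mixture_refs.setdefault(row["seq_id"], None)
        # reconstruct each source fragment and check damaged positions
        for read in reads[:500]:
            row = refs_by_read.loc[read.read_id]
            if not row["damaged_positions"]:
                continue
            for pos in map(int, row["damaged_positions"].split(",")):
                assert read.seq[pos] in "TA"  # C>T or G>A product

    def test_contaminant_reads_undamaged(self, two_taxon_mixture):
        contaminant = make_taxon("modern", "Homo", 1.0, seed=99)
        cfg = SimConfig(seed=8, n_reads=2000, error_rate=0.0, contamination_fraction=0.3)
        _, truth, _ = simulate_metagenome(
            two_taxon_mixture, FragmentModel(), DamageModel(), cfg, contaminant
        )
        contam = truth[truth["is_contaminant"]]
        assert len(contam) > 0
        assert (contam["damaged_positions"] == "").all()

    def test_short_reference_rejected(self):
        short = TaxonSpec(
            "tiny", "Tiny sp", "Tiny", 1.0,
            [ReferenceSeq("tiny_ref", "mitochondrion", "ACGT" * 10)],
        )
        with pytest.raises(ValueError, match="tiny_ref"):
            simulate_metagenome(
                [short], FragmentModel(), DamageModel(), SimConfig(seed=1, n_reads=10)
            )

    def test_truth_conservation(self, damaged_simulation):
        reads, truth, alns = damaged_simulation
        assert len(reads) == len(truth) == len(alns)
        assert (truth["end"] - truth["start"]).tolist() == [
            len(r.seq) for r in reads
        ]


class TestSexReadset:
    LAYOUT = {
        "chr1": ("autosome", 100_000),
        "chrX": ("chrX", 50_000),
        "chrY": ("chrY", 50_000),
    }

    def test_xy_ratio_near_half(self):
        counts = simulate_sex_readset("XY", 100_000, self.LAYOUT, seed=1)
        ry = counts["chrY"] / (counts["chrX"] + counts["chrY"])
        assert abs(ry - 0.5) < 0.01  # binomial oracle at n=1e5

    def test_xy_sex_chromosomes_at_half_autosomal_rate(self):
        counts = simulate_sex_readset("XY", 200_000, self.LAYOUT, seed=2)
        auto_rate = counts["chr1"] / self.LAYOUT["chr1"][1]
        x_rate = counts["chrX"] / self.LAYOUT["chrX"][1]
        assert x_rate == pytest.approx(auto_rate / 2, rel=0.1)

    def test_xx_no_noise_yields_zero_y(self):
        counts = simulate_sex_readset("XX", 50_000, self.LAYOUT, seed=3, y_noise=0.0)
        assert counts["chrY"] == 0

    def test_zero_reads_error(self):
        with pytest.raises(ValueError):
            simulate_sex_readset("XY", 0, self.LAYOUT, seed=1)


def _diag_sites(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": ["MT"] * n,
            "pos": range(1, n + 1),
            "ref": ["A"] * n,
            "endo_allele": ["A"] * n,
            "contam_allele": ["G"] * n,
            "diagnostic": [True] * n,
        }
    )


class TestSimulatePileup:
    def test_no_contamination_monoallelic(self):
        pileup, _ = simulate_pileup(_diag_sites(20), 50, 0.0, seed=4)
        assert (pileup["G"] == 0).all()
        assert (pileup[["C", "T"]].to_numpy() == 0).all()

    def test_full_contamination_is_contaminant_haplotype(self):
        pileup, _ = simulate_pileup(_diag_sites(20), 50, 1.0, seed=4)
        assert (pileup["A"] == 0).all()
        assert (pileup["G"] > 0).sum() == 20 - (pileup["G"] == 0).sum()

    def test_minority_fraction_recovers_contamination(self):
        pileup, _ = simulate_pileup(_diag_sites(50), 100, 0.10, seed=5)
        minority = pileup["G"].sum()
        total = pileup[["A", "C", "G", "T"]].to_numpy().sum()
        assert abs(minority / total - 0.10) < 0.02

    def test_no_diagnostic_sites_error(self):
        sites = _diag_sites(5)
        sites["diagnostic"] = False
        with pytest.raises(ValueError, match="diagnostic"):
            simulate_pileup(sites, 50, 0.1, seed=1)


class TestSynthTaxReport:
    def test_single_short_read_kmer_cap(self):
        taxon = make_taxon("solo", "Solo", 1.0, length=5000, seed=7)
        truth = pd.DataFrame(
            [{"read_id": "r0", "taxon_id": "solo", "seq_id": "solo_ref",
              "start": 100, "end": 150, "strand": "+",
              "damaged_positions": "", "is_contaminant": False}]
        )
        report = synth_tax_report(truth, [taxon], k=31)
        species = report[report["rank"] == "species"].iloc[0]
        assert species["kmers"] == 50 - 31 + 1  # 20

    def test_duplicate_reads_double_dup_not_kmers(self):
        taxon = make_taxon("solo", "Solo", 1.0, length=5000, seed=7)
        one = pd.DataFrame(
            [{"read_id": f"r{i}", "taxon_id": "solo", "seq_id": "solo_ref",
              "start": 100, "end": 160, "strand": "+",
              "damaged_positions": "", "is_contaminant": False}
             for i in range(1)]
        )
        two = pd.concat([one, one.assign(read_id="r_dup")], ignore_index=True)
        r1 = synth_tax_report(one, [taxon]).query("rank == 'species'").iloc[0]
        r2 = synth_tax_report(two, [taxon]).query("rank == 'species'").iloc[0]
        assert r2["kmers"] == r1["kmers"]
        assert r2["dup"] == pytest.approx(2 * r1["dup"])

    def test_spread_reads_have_more_kmers_than_clonal(self):
        taxon = make_taxon("solo", "Solo", 1.0, length=10_000, seed=7)
        spread = pd.DataFrame(
            [{"read_id": f"s{i}", "taxon_id": "solo", "seq_id": "solo_ref",
              "start": 200 * i, "end": 200 * i + 60, "strand": "+",
              "damaged_positions": "", "is_contaminant": False}
             for i in range(20)]
        )
        clonal = spread.copy()
        clonal["start"] = 100
        clonal["end"] = 160
        k_spread = synth_tax_report(spread, [taxon]).query("rank=='species'").iloc[0]["kmers"]
        k_clonal = synth_tax_report(clonal, [taxon]).query("rank=='species'").iloc[0]["kmers"]
        assert k_spread > k_clonal

    def test_small_k_rejected(self):
        taxon = make_taxon("solo", "Solo", 1.0)
        with pytest.raises(ValueError):
            synth_tax_report(pd.DataFrame(), [taxon], k=15)


class TestSynthPSMTable:
    def test_peptides_are_true_substrings_with_truth_labels(self):
        db, diag = make_two_species_protein_db(seed=1)
        table = synth_psm_table(db, diag, n_psms=100, seed=2)
        for _, row in table.iterrows():
            acc = row["accessions"]
            sp, prot = db[acc]
            assert row["peptide"] in prot
            assert sp == row["true_species"]

    def test_determinism(self):
        db, diag = make_two_species_protein_db(seed=1)
        a = synth_psm_table(db, diag, n_psms=100, seed=3)
        b = synth_psm_table(db, diag, n_psms=100, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_diagnostic_position_rejected(self):
        db, diag = make_two_species_protein_db(seed=1)
        # overwrite species B's protein with species A's: position no longer differs
        db["PROT000_B"] = (db["PROT000_B"][0], db["PROT000_A"][1])
        with pytest.raises(ValueError, match="identical"):
            synth_psm_table(db, diag, n_psms=10, seed=1)
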