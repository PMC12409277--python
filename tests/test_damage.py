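"""Damage profiling tests: by-construction single-read cells, simulator
parameter recovery within binomial confidence bands, strand invariance,
additivity, MD-vs-FASTA agreement, distribution tables, and the group
comparison statistics against closed-form oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from sedsift.core import AlignmentRecord, revcomp
from sedsift.damage import (
    DamageProfile,
    compare_damage,
    distributions,
    fit_damage_model,
    misincorporation_profile,
    terminal_damage,
)
from sedsift.simulate import (
    DamageModel,
    FragmentModel,
    ReferenceSeq,
    SimConfig,
    TaxonSpec,
    simulate_metagenome,
)
from conftest import random_sequence


def plain_aln(seq, md=None, strand="+", ref_id="ref", pos=0, nm=0):
    return AlignmentRecord("r", ref_id, pos, strand, f"{len(seq)}M", nm, 60, seq, md)


class TestMisincorporationProfile:
    def test_identical_read_all_frequencies_zero(self):
        p = misincorporation_profile([plain_aln("ACGTACGTAC", md="10")])
        for end in ("5p", "3p"):
            for pos in range(1, 11):
                for ref, read in (("C", "T"), ("G", "A")):
                    f = p.frequency(end, pos, ref, read)
                    assert f == 0.0 or math.isnan(f)

    def test_single_terminal_ct_by_construction(self):
        # reference CCGTA, read TCGTA: C>T at 5' position 1
        p = misincorporation_profile([plain_aln("TCGTA", md="0C4")])
        assert p.frequency("5p", 1, "C", "T") == 1.0
        assert p.opportunities[("5p", 1, "C")] == 1

    def test_minus_strand_flipped_into_read_orientation(self):
        # Reference GGCAT; read (ref orientation) AGCAT => ref G read A at
        # ref position 1. On the minus strand the sequenced read is
        # revcomp(AGCAT) = ATGCT with 5' C>T at position... the flip must
        # place the substitution as C>T at 5' position 5.
        p = misincorporation_profile([plain_aln("AGCAT", md="0G4", strand="-")])
        assert p.frequency("5p", 5, "C", "T") == 1.0

    def test_strand_invariance(self):
        rng = np.random.default_rng(0)
        ref = random_sequence(rng, 6000)
        taxon = TaxonSpec("t", "T sp", "T", 1.0,
                          [ReferenceSeq("ref", "mitochondrion", ref)])
        _, _, alns = simulate_metagenome(
            [taxon], FragmentModel(), DamageModel(),
            SimConfig(seed=2, n_reads=400, error_rate=0.0),
        )
        p = misincorporation_profile(alns)
        # flip every alignment onto the reverse-complemented reference
        flipped = []
        for a in alns:
            new_strand = "-" if a.strand == "+" else "+"
            new_pos = len(ref) - a.end
            flipped.append(
                AlignmentRecord(a.read_id, "ref_rc", new_pos, new_strand,
                                a.cigar, a.nm, a.mapq, revcomp(a.seq))
            )
        p_flipped = misincorporation_profile(
            flipped, references={"ref_rc": revcomp(ref)}
        )
        for end in ("5p", "3p"):
            for pos in (1, 2, 3, 5, 10):
                for ref_b, read_b in (("C", "T"), ("G", "A"), ("A", "G")):
                    assert p.counts.get((end, pos, ref_b, read_b), 0) == \
                        p_flipped.counts.get((end, pos, ref_b, read_b), 0)

    def test_additivity(self, damaged_simulation):
        _, _, alns = damaged_simulation
        half = len(alns) // 2
        pa = misincorporation_profile(alns[:half])
        pb = misincorporation_profile(alns[half:])
        total = misincorporation_profile(alns)
        merged = pa.add(pb)
        assert merged.counts == total.counts
        assert merged.opportunities == total.opportunities

    def test_md_and_fasta_paths_agree(self, damaged_simulation, two_taxon_mixture):
        _, _, alns = damaged_simulation
        refs = {r.seq_id: r.seq for t in two_taxon_mixture for r in t.references}
        with_md = misincorporation_profile(alns[:300])
        stripped = [
            AlignmentRecord(a.read_id, a.ref_id, a.pos, a.strand, a.cigar,
                            a.nm, a.mapq, a.seq, md=None)
            for a in alns[:300]
        ]
        from_fasta = misincorporation_profile(stripped, references=refs)
        assert with_md.counts == from_fasta.counts
        assert with_md.opportunities == from_fasta.opportunities

    def test_alignment_without_reference_info_skipped(self):
        p = misincorporation_profile([plain_aln("ACGT", md=None)])
        assert p.n_skipped == 1 and p.n_reads == 0

    def test_parameter_recovery_within_binomial_ci(self):
        """20,000 simulated reads at delta5=0.2, decay=0.6: the estimated
        position-wise C>T frequency must sit inside the 99% binomial CI of
        the model curve at positions 1-10."""
        rng = np.random.default_rng(5)
        ref = random_sequence(rng, 30_000)
        taxon = TaxonSpec("t", "T sp", "T", 1.0,
                          [ReferenceSeq("ref", "mitochondrion", ref)])
        dmg = DamageModel(delta5=0.2, decay=0.6, delta_base=0.01)
        _, _, alns = simulate_metagenome(
            [taxon], FragmentModel(), dmg,
            SimConfig(seed=6, n_reads=20_000, error_rate=0.0),
        )
        profile = misincorporation_profile(alns)
        for pos in range(1, 11):
            opp = profile.opportunities[("5p", pos, "C")]
            obs = profile.counts.get(("5p", pos, "C", "T"), 0)
            lo, hi = sps.binom.interval(0.99, opp, dmg.rate(pos))
            assert lo <= obs <= hi, f"position {pos}: {obs} outside [{lo},{hi}]"
        # weighted least-squares recovery of the model parameters
        d5, decay, _ = fit_damage_model(profile)
        assert d5 == pytest.approx(0.2, rel=0.10)
        assert decay == pytest.approx(0.6, rel=0.10)


class TestTerminalDamage:
    def _uniform_profile(self, freq, k=3, opp=1000, n_reads=500):
        p = DamageProfile()
        p.n_reads = n_reads
        for i in range(1, k + 1):
            p.opportunities[("5p", i, "C")] = opp
            p.counts[("5p", i, "C", "T")] = int(freq * opp)
            p.opportunities[("3p", i, "G")] = opp
            p.counts[("3p", i, "G", "A")] = int(freq * opp)
        return p

    def test_uniform_cells_give_that_frequency(self):
        s = terminal_damage(self._uniform_profile(0.12), k=3)
        assert s.value == pytest.approx(0.12)

    def test_read_gate_boundary_is_strict(self):
        assert not terminal_damage(self._uniform_profile(0.1, n_reads=100), 3).gate_passed
        assert terminal_damage(self._uniform_profile(0.1, n_reads=101), 3).gate_passed

    def test_zero_opportunities_flagged_undefined(self):
        p = DamageProfile()
        p.n_reads = 500
        s = terminal_damage(p, k=3)
        assert s.value is None

    def test_contaminant_only_reads_at_background_floor(self, two_taxon_mixture):
        from conftest import make_taxon

        contaminant = make_taxon("modern", "Homo", 1.0, length=6000, seed=50)
        _, truth, alns = simulate_metagenome(
            two_taxon_mixture, FragmentModel(),
            DamageModel(delta5=0.2, decay=0.6, delta_base=0.01),
            SimConfig(seed=51, n_reads=3000, error_rate=0.0,
                      contamination_fraction=0.5),
            contaminant,
        )
        contam_ids = set(truth.loc[truth["is_contaminant"], "read_id"])
        profile = misincorporation_profile(
            [a for a in alns if a.read_id in contam_ids]
        )
        s = terminal_damage(profile, k=3)
        assert s.value == pytest.approx(0.0, abs=1e-9)  # no damage at all


class TestDistributions:
    def test_single_read_tables(self):
        d = distributions([plain_aln("G" * 20 + "C" * 22, md="42")])
        assert d["length"].to_dict() == {42: 1}
        assert d["gc"].iloc[0] == 1.0

    def test_lognormal_mean_recovered(self, damaged_simulation):
        _, _, alns = damaged_simulation
        frag = FragmentModel()
        d = distributions(alns)
        lengths = np.repeat(d["length"].index.to_numpy(), d["length"].values)
        # truncation shifts the mean slightly; compare against the
        # empirical mean of an independent large sample of the same model
        oracle = frag.sample(np.random.default_rng(123), 200_000)
        se = oracle.std() / math.sqrt(len(lengths))
        assert abs(lengths.mean() - oracle.mean()) < 3 * se


class TestCompareDamage:
    def test_identical_groups_t_zero_p_one(self):
        g = {"a": [0.1, 0.2, 0.3], "b": [0.1, 0.2, 0.3]}
        res = compare_damage(g)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_welch_matches_closed_form(self):
        a = [27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6]
        b = [27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8, 20.2]
        res = compare_damage({"a": a, "b": b})
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t = (ma - mb) / math.sqrt(va / len(a) + vb / len(b))
        df = (va / len(a) + vb / len(b)) ** 2 / (
            (va / len(a)) ** 2 / (len(a) - 1) + (vb / len(b)) ** 2 / (len(b) - 1)
        )
        p = 2 * sps.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t, abs=1e-6)
        assert res.df == pytest.approx(df, abs=1e-6)
        assert res.p_value == pytest.approx(p, abs=1e-6)

    def test_three_groups_anova_with_reference_contrasts(self):
        rng = np.random.default_rng(9)
        groups = {
            "soil": list(rng.normal(0.05, 0.02, 10)),
            "gut": list(rng.normal(0.15, 0.02, 10)),
            "oral": list(rng.normal(0.08, 0.02, 10)),
        }
        res = compare_damage(groups, reference_group="soil")
        assert res.test == "anova"
        f, p = sps.f_oneway(*groups.values())
        assert res.statistic == pytest.approx(f)
        assert set(res.contrasts["group"]) == {"gut", "oral"}

    def test_small_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = compare_damage({"a": [1.0], "b": [0.1, 0.2, 0.3],
                                  "c": [0.4, 0.5, 0.6]})
        assert res.test == "welch-t"

    def test_power_gut_vs_soil(self):
        """Damage 0.15 vs 0.05 (sd 0.02, n=10 per group) is detected at
        p < 0.05 in at least 95% of 200 simulations."""
        rng = np.random.default_rng(10)
        hits = 0
        for _ in range(200):
            g = {"gut": list(rng.normal(0.15, 0.02, 10)),
                 "soil": list(rng.normal(0.05, 0.02, 10))}
            if compare_damage(g).p_value < 0.05:
                hits += 1
        assert hits >= 190
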