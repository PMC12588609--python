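"""Tests for the central-fusion cohort simulator."""

import numpy as np
import pytest
import scipy.stats

from csdscan import simcohort
from csdscan.simcohort import (
    CohortConfig,
    CSDModel,
    LineConfig,
    MeiosisParams,
    ReadModel,
)
from csdscan._util import stream

CHROMS = {"chr1": 200_000}


def small_founder(anc_het_fraction=1.0, seed=0, blocks=None):
    return simcohort.simulate_founder(
        CHROMS, snp_density=1e-3, anc_het_fraction=anc_het_fraction, seed=seed,
        het_block_bp=blocks,
    )


class TestSimulateFounder:
    def test_fraction_one_all_heterozygous(self):
        fg = small_founder(1.0)
        assert fg.anc_het_mask["chr1"].all()
        al = fg.founder_alleles["chr1"]
        assert (al[:, 0] != al[:, 1]).all()

    def test_fraction_zero_no_heterozygous(self):
        fg = small_founder(0.0)
        assert not fg.anc_het_mask["chr1"].any()

    def test_deterministic_site_list(self):
        a = simcohort.simulate_founder({"chr1": 1_000_000}, 1e-3, 0.5, seed=3)
        b = simcohort.simulate_founder({"chr1": 1_000_000}, 1e-3, 0.5, seed=3)
        np.testing.assert_array_equal(a.snp_positions["chr1"], b.snp_positions["chr1"])
        np.testing.assert_array_equal(a.anc_het_mask["chr1"], b.anc_het_mask["chr1"])

    def test_positions_strictly_increasing(self):
        fg = small_founder(0.5, seed=11)
        assert (np.diff(fg.snp_positions["chr1"]) > 0).all()

    @pytest.mark.parametrize(
        "chroms,density,frac",
        [({}, 1e-3, 0.5), ({"chr1": 0}, 1e-3, 0.5), (CHROMS, 0, 0.5), (CHROMS, 1e-3, 1.5)],
    )
    def test_invalid_parameters(self, chroms, density, frac):
        with pytest.raises(ValueError):
            simcohort.simulate_founder(chroms, density, frac, seed=0)


class _ScriptedRng:
    """Duck-typed generator driving meiosis with a fixed crossover script."""

    def __init__(self, breakpoints, fidelity_draws, col_draws, haploid=False):
        self.breakpoints = list(breakpoints)
        self.fidelity_draws = list(fidelity_draws)
        self.col_draws = list(col_draws)
        self.haploid = haploid

    def random(self):
        if self.haploid is not None:
            v = 0.0 if self.haploid else 1.0
            self.haploid = None  # first random() call decides ploidy
            return v
        return self.fidelity_draws.pop(0)

    def poisson(self, lam):
        return len(self.breakpoints)

    def uniform(self, lo, hi, size):
        return np.array(self.breakpoints[:size], dtype=float)

    def integers(self, lo, hi, size=None):
        return self.col_draws.pop(0)


class TestCentralFusion:
    def founder(self):
        return small_founder(1.0, seed=2)

    def test_no_crossover_restores_mother(self):
        fg = self.founder()
        params = MeiosisParams(crossover_rate=0.0, coinheritance_fidelity=0.5,
                               haploid_male_rate=0.0)
        rng = stream(0, "t")
        child, tracts, ploidy = simcohort.reproduce_central_fusion(
            fg.founder_alleles, fg.chrom_lengths, params, rng, fg.snp_positions
        )
        assert ploidy == 2 and tracts == []
        np.testing.assert_array_equal(child["chr1"], fg.founder_alleles["chr1"])

    def test_full_fidelity_never_loses_heterozygosity(self):
        fg = self.founder()
        params = MeiosisParams(crossover_rate=5.0, coinheritance_fidelity=1.0,
                               haploid_male_rate=0.0)
        for seed in range(20):
            child, tracts, _ = simcohort.reproduce_central_fusion(
                fg.founder_alleles, fg.chrom_lengths, params, stream(seed, "t"),
                fg.snp_positions,
            )
            assert tracts == []
            assert (child["chr1"][:, 0] != child["chr1"][:, 1]).all()

    def test_single_forced_crossover_tract_structure(self):
        """One crossover without co-inheritance: one tract from the breakpoint
        to the chromosome end, homozygous for one maternal allele.

        Scripted draws enumerate both chromatid choices; the oracle is the
        four-outcome single-crossover tetrad, in which the two non-faithful
        fusions are homozygous distal to the breakpoint for one or the other
        maternal allele and heterozygous proximal to it.
        """
        fg = self.founder()
        x = 100_000
        pos = fg.snp_positions["chr1"]
        mg = fg.founder_alleles["chr1"]
        params = MeiosisParams(crossover_rate=1.0, coinheritance_fidelity=0.0,
                               haploid_male_rate=0.0)
        seen = set()
        for col in (0, 1):
            rng = _ScriptedRng([x], fidelity_draws=[0.5], col_draws=[col], haploid=False)
            child, tracts, ploidy = simcohort.reproduce_central_fusion(
                fg.founder_alleles, fg.chrom_lengths, params, rng, fg.snp_positions
            )
            assert ploidy == 2
            assert len(tracts) == 1
            c, start, end, allele = tracts[0]
            assert (c, start, end) == ("chr1", x, fg.chrom_lengths["chr1"])
            distal = pos - 1 >= x
            # homozygous for the chosen maternal allele distal to the breakpoint
            np.testing.assert_array_equal(child["chr1"][distal, 0], mg[distal, col])
            np.testing.assert_array_equal(child["chr1"][distal, 1], mg[distal, col])
            # heterozygosity intact proximal to it
            np.testing.assert_array_equal(child["chr1"][~distal], mg[~distal])
            seen.add(allele)
        assert seen == {0, 1}

    def test_haploid_mother_rejected(self):
        fg = self.founder()
        hap = {"chr1": fg.founder_alleles["chr1"][:, 0]}
        with pytest.raises(ValueError):
            simcohort.reproduce_central_fusion(
                hap, fg.chrom_lengths, MeiosisParams(), stream(0, "t"),
                fg.snp_positions,
            )

    def test_tracts_bounded_by_breakpoint_and_chromosome_end(self):
        fg = self.founder()
        params = MeiosisParams(crossover_rate=2.0, coinheritance_fidelity=0.0,
                               haploid_male_rate=0.0)
        for seed in range(50):
            _, tracts, _ = simcohort.reproduce_central_fusion(
                fg.founder_alleles, fg.chrom_lengths, params, stream(seed, "t"),
                fg.snp_positions,
            )
            for c, start, end, _ in tracts:
                assert 0 <= start < end == fg.chrom_lengths[c]

    def test_loh_allele_balance(self):
        """Across many meioses the retained allele is either maternal allele
        about half the time (binomial test over >=200 tracts)."""
        fg = self.founder()
        params = MeiosisParams(crossover_rate=1.0, coinheritance_fidelity=0.0,
                               haploid_male_rate=0.0)
        alleles = []
        seed = 0
        while len(alleles) < 200:
            _, tracts, _ = simcohort.reproduce_central_fusion(
                fg.founder_alleles, fg.chrom_lengths, params, stream(seed, "t"),
                fg.snp_positions,
            )
            alleles.extend(t[3] for t in tracts)
            seed += 1
        k = sum(alleles)
        p = scipy.stats.binomtest(k, len(alleles), 0.5).pvalue
        assert p > 1e-3


class TestAssignSex:
    def setup_method(self):
        self.fg = small_founder(1.0, seed=5)
        self.pos = self.fg.snp_positions

    def test_haploid_is_male(self):
        model = CSDModel(loci=[("chr1", 0, 200_000)])
        g = {"chr1": self.fg.founder_alleles["chr1"][:, 0]}
        assert simcohort.assign_sex(g, 1, model, stream(0, "t"), self.pos) == "male"

    def test_heterozygous_diploid_is_female(self):
        model = CSDModel(loci=[("chr1", 0, 200_000)], stochastic_male_rate=0.0)
        g = {"chr1": self.fg.founder_alleles["chr1"].copy()}
        assert simcohort.assign_sex(g, 2, model, stream(0, "t"), self.pos) == "female"

    def test_homozygous_diploid_is_male(self):
        model = CSDModel(loci=[("chr1", 0, 200_000)], stochastic_male_rate=0.0)
        al = self.fg.founder_alleles["chr1"]
        g = {"chr1": np.stack([al[:, 0], al[:, 0]], axis=1)}
        assert simcohort.assign_sex(g, 2, model, stream(0, "t"), self.pos) == "male"

    def test_multi_locus_rule(self):
        """Heterozygosity at any one locus suffices for female development."""
        model = CSDModel(
            loci=[("chr1", 0, 100_000), ("chr1", 100_000, 200_000)],
            rule="multi",
            stochastic_male_rate=0.0,
        )
        al = self.fg.founder_alleles["chr1"]
        pos = self.pos["chr1"]
        half = pos - 1 < 100_000
        g = al.copy()
        g[half, 1] = g[half, 0]  # locus A homozygous, locus B heterozygous
        assert simcohort.assign_sex({"chr1": g}, 2, model, stream(0, "t"), self.pos) == "female"
        g2 = np.stack([al[:, 0], al[:, 0]], axis=1)  # both homozygous
        assert simcohort.assign_sex({"chr1": g2}, 2, model, stream(0, "t"), self.pos) == "male"

    def test_locus_without_snps_rejected(self):
        pos = self.pos["chr1"]
        gap_start = int(pos.max()) + 10
        model = CSDModel(loci=[("chr1", gap_start, gap_start + 5)])
        g = {"chr1": self.fg.founder_alleles["chr1"]}
        with pytest.raises(ValueError):
            simcohort.assign_sex(g, 2, model, stream(0, "t"), self.pos)

    def test_stochastic_males_occur_at_given_rate(self):
        model = CSDModel(loci=[("chr1", 0, 200_000)], stochastic_male_rate=0.5)
        g = {"chr1": self.fg.founder_alleles["chr1"]}
        sexes = [
            simcohort.assign_sex(g, 2, model, stream(s, "x"), self.pos)
            for s in range(200)
        ]
        k = sexes.count("male")
        assert scipy.stats.binomtest(k, 200, 0.5).pvalue > 1e-3


class TestEmitGenotypeCalls:
    def _individuals(self, fg, n=4):
        out = []
        for i in range(n):
            out.append(
                simcohort.Individual(
                    f"s{i}", "female", 2, "c1", "A",
                    {"chr1": fg.founder_alleles["chr1"].copy()}, [],
                )
            )
        return out

    def test_noiseless_calls_match_truth(self):
        fg = small_founder(0.7, seed=9)
        inds = self._individuals(fg)
        rm = ReadModel(mean_depth=50, depth_dispersion=0.0, base_error=0.0)
        vt = simcohort.emit_genotype_calls(inds, fg, rm, seed=1)
        truth = fg.founder_alleles["chr1"]
        for j in range(len(inds)):
            called = vt.gt[:, j, :]
            ok = called[:, 0] >= 0
            assert ok.all()
            np.testing.assert_array_equal(np.sort(called, axis=1), np.sort(truth, axis=1))

    def test_haploid_heterozygous_in_collapsed_region(self):
        fg = small_founder(1.0, seed=9)
        hap = simcohort.Individual(
            "h1", "male", 1, "c1", "A",
            {"chr1": fg.founder_alleles["chr1"][:, 0].copy()}, [],
        )
        rm = ReadModel(
            mean_depth=50, depth_dispersion=0.0, base_error=0.0,
            collapsed_regions=[("chr1", 50_000, 60_000)],
        )
        vt = simcohort.emit_genotype_calls([hap], fg, rm, seed=1)
        inside = (vt.pos - 1 >= 50_000) & (vt.pos - 1 < 60_000)
        assert inside.any()
        assert vt.is_het[inside, 0].all()
        # outside: single-allele hemizygous calls
        assert (vt.gt[~inside, 0, 1] == -2).all()

    def test_zero_depth_all_missing(self):
        fg = small_founder(1.0, seed=9)
        inds = self._individuals(fg, n=2)
        rm = ReadModel(mean_depth=0.0, depth_dispersion=0.0, base_error=0.0)
        vt = simcohort.emit_genotype_calls(inds, fg, rm, seed=1)
        assert vt.is_missing.all()


class TestSimulateCohort:
    def small_config(self):
        return CohortConfig(
            chrom_lengths={"chr1": 300_000},
            csd=CSDModel(loci=[("chr1", 100_000, 150_000)], stochastic_male_rate=0.0),
            lines=[LineConfig(name="A", n_colonies=2, offspring_per_colony=10)],
            meiosis=MeiosisParams(crossover_rate=1.0, coinheritance_fidelity=0.8,
                                  haploid_male_rate=0.1),
            reads=ReadModel(collapsed_regions=[]),
        )

    def test_vcf_byte_identical_across_runs(self, tmp_path):
        cfg = self.small_config()
        simcohort.simulate_cohort(cfg, seed=4, outdir=tmp_path / "a")
        simcohort.simulate_cohort(cfg, seed=4, outdir=tmp_path / "b")
        assert (tmp_path / "a/cohort.vcf").read_bytes() == (tmp_path / "b/cohort.vcf").read_bytes()
        assert (tmp_path / "a/metadata.tsv").read_text() == (tmp_path / "b/metadata.tsv").read_text()

    def test_truth_files_written(self, tmp_path):
        cfg = self.small_config()
        vt, meta, truth = simcohort.simulate_cohort(cfg, seed=4, outdir=tmp_path / "o")
        assert (tmp_path / "o/loh_tracts.tsv").exists()
        assert (tmp_path / "o/planted_loci.tsv").exists()
        assert (tmp_path / "o/sim_config.txt").exists()
        assert len(meta) == 20

    def test_diploid_male_truth_covers_planted_locus(self):
        """With no stochastic males, every diploid male's LOH tracts (or
        founder homozygosity) cover the planted locus: brute-force interval
        containment against the truth files."""
        cfg = self.small_config()
        found = 0
        for seed in range(30):
            vt, meta, truth = simcohort.build_cohort(cfg, seed=seed)
            males = meta[(meta.sex == "male") & (meta.ploidy == 2)]
            (c, s, e) = truth.csd.loci[0]
            pos = truth.founders["A"].snp_positions[c]
            locus_snps = pos[(pos - 1 >= s) & (pos - 1 < e)]
            first_snp0 = int(locus_snps.min()) - 1
            for sid in males["sample_id"]:
                tr = truth.loh_tracts[truth.loh_tracts.sample_id == sid]
                # a tract makes a male iff it spans every locus SNP
                covered = any(
                    (row.chrom == c) and (row.start <= first_snp0) and (row.end >= e)
                    for row in tr.itertuples()
                )
                assert covered, f"diploid male {sid} lacks LOH across the locus"
                found += 1
        assert found >= 3  # diploid males are rare but must occur across seeds

    def test_sexes_emergent_and_mostly_female(self):
        cfg = self.small_config()
        _, meta, _ = simcohort.build_cohort(cfg, seed=1)
        assert (meta.sex == "female").sum() > len(meta) / 2

    def test_mapping_panel_composition(self):
        from csdscan import fixtures

        vt, meta, truth = simcohort.build_mapping_panel(
            fixtures.recovery_config(), seed=3,
            n_diploid_males=4, n_diploid_females=6, n_haploid_males=1,
        )
        counts = meta.groupby(["sex", "ploidy"]).size().to_dict()
        assert counts == {("female", 2): 6, ("male", 1): 1, ("male", 2): 4}
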