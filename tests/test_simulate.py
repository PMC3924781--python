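"""Population simulator: map construction, meiosis, backcross arithmetic,
phenotype generation and heritability calibration."""

import numpy as np
import pytest
from scipy import stats

from bcqtl.probability import map_distance
from bcqtl.simulate import (
    EpistasisEffect,
    LinkageMap,
    ProgenyData,
    QtlEffect,
    QtlScenario,
    build_standard_map,
    calibrate_residual_variance,
    genetic_values,
    seven_qtl_scenario,
    simulate_dataset,
    simulate_double_backcross,
    simulate_lines,
    simulate_phenotypes,
)


class TestLinkageMap:
    def test_standard_map_shape(self):
        m = build_standard_map()
        assert m.n_chrom == 5
        assert m.n_markers == 55
        for pos in m.positions:
            assert pos[0] == 0.0
            assert pos[-1] == 100.0
            assert np.all(np.diff(pos) == 10.0)

    def test_roundtrip_frame(self):
        m = build_standard_map(3, 4, 5.0)
        m2 = LinkageMap.from_frame(m.to_frame())
        assert m2.chrom_names == m.chrom_names
        assert all(np.allclose(a, b) for a, b in zip(m.positions, m2.positions))

    def test_validation(self):
        with pytest.raises(ValueError, match="strictly increase"):
            LinkageMap(["C1"], [["a", "b"]], [np.array([5.0, 5.0])])
        with pytest.raises(ValueError, match="duplicate"):
            LinkageMap(
                ["C1", "C2"], [["a"], ["a"]], [np.array([0.0]), np.array([0.0])]
            )


class TestScenario:
    def test_builtin_values(self):
        s = seven_qtl_scenario()
        assert len(s.qtls) == 7 and len(s.epistasis) == 3
        assert s.qtl("Q1").a == -2.78 and s.qtl("Q1").d == -3.08
        assert s.qtl("Q1").chromosome == "C1" and s.qtl("Q1").position_cm == 44.0
        assert s.qtl("Q4").de == (-2.10, 2.50, -0.40)
        eq3 = next(e for e in s.epistasis if e.name == "EQ3")
        assert eq3.aa == -2.60 and eq3.aae == (0.0, 0.0, 0.0)
        eq1 = next(e for e in s.epistasis if e.name == "EQ1")
        assert eq1.aa == -3.09 and eq1.aae == (2.52, -0.16, -2.36)
        assert s.heritability == 0.60 and s.n_env == 3
        # Q6/Q7 are purely epistatic
        assert [q.name for q in s.main_effect_qtls()] == ["Q1", "Q2", "Q3", "Q4", "Q5"]

    def test_without_epistasis(self):
        s = seven_qtl_scenario().without_epistasis()
        assert s.epistasis == []
        assert s.qtl("Q1").a == -2.78

    def test_validation(self):
        with pytest.raises(ValueError, match="heritability"):
            QtlScenario([], [], n_env=1, heritability=0.0)
        with pytest.raises(ValueError, match="undeclared"):
            QtlScenario(
                [QtlEffect("Q1", "C1", 10.0, a=1.0)],
                [EpistasisEffect("E", "Q1", "QX", aa=1.0)],
                n_env=1, heritability=0.5,
            )
        with pytest.raises(ValueError, match="length"):
            QtlScenario(
                [QtlEffect("Q1", "C1", 10.0, ae=(1.0,))], [],
                n_env=2, heritability=0.5,
            )


class TestLines:
    def test_dh_lines_homozygous_by_construction(self):
        # alleles are single parental origins; progeny of a line x its own
        # parent must be homozygous at every locus
        lmap = build_standard_map(2, 5)
        alleles, _ = simulate_lines(lmap, 50, 3)
        assert set(np.unique(alleles)) <= {0, 1}

    def test_allele_frequency(self):
        lmap = build_standard_map(1, 2)
        alleles, _ = simulate_lines(lmap, 10000, 7)
        freq = (alleles[:, 0] == 0).mean()
        se = 0.5 / np.sqrt(10000)
        assert abs(freq - 0.5) < 3 * se

    def test_recombinant_fraction_10cm(self):
        lmap = build_standard_map(1, 2)
        alleles, _ = simulate_lines(lmap, 10000, 11)
        rec = (alleles[:, 0] != alleles[:, 1]).mean()
        se = np.sqrt(0.0906 * (1 - 0.0906) / 10000)
        assert abs(rec - 0.090635) < 3 * se

    def test_map_recovery(self):
        lmap = build_standard_map(1, 11)
        alleles, _ = simulate_lines(lmap, 10000, 13)
        rec = (alleles[:, :-1] != alleles[:, 1:]).mean(axis=0)
        cm = map_distance(rec)
        # ~0.35 cM SE per interval at n=10000; 3 SE per interval, tighter mean
        assert np.all(np.abs(cm - 10.0) < 1.05)
        assert abs(cm.mean() - 10.0) < 0.7

    def test_ri_lines_expanded_recombination(self):
        lmap = build_standard_map(1, 2)
        alleles, _ = simulate_lines(lmap, 20000, 17, line_type="RI")
        r = 0.090635
        expect = 2 * r / (1 + 2 * r)
        rec = (alleles[:, 0] != alleles[:, 1]).mean()
        se = np.sqrt(expect * (1 - expect) / 20000)
        assert abs(rec - expect) < 3 * se

    def test_segregation_chi_square(self):
        lmap = build_standard_map(1, 3)
        alleles, _ = simulate_lines(lmap, 10000, 19)
        for j in range(3):
            n0 = int((alleles[:, j] == 0).sum())
            chi2 = (n0 - 5000) ** 2 / 5000 + (10000 - n0 - 5000) ** 2 / 5000
            assert chi2 < stats.chi2.ppf(0.999, 1)


class TestDoubleBackcross:
    def test_counts_and_labels(self):
        lmap = build_standard_map(1, 3)
        alleles, _ = simulate_lines(lmap, 300, 23)
        prog = simulate_double_backcross(lmap, alleles, 150, 150, 24)
        assert prog.n_individuals == 300
        assert (prog.origin == 0).sum() == 150

    def test_cross_arithmetic(self):
        lmap = build_standard_map(1, 2)
        alleles = np.array([[0, 1]], dtype=np.uint8)
        prog = simulate_double_backcross(lmap, alleles, 1, 0, 1)
        assert prog.genotypes[0, 0] == 2  # P1 allele + P1 parent = homozygote
        assert prog.genotypes[0, 1] == 1  # P2 allele + P1 parent = heterozygote
        prog2 = simulate_double_backcross(lmap, alleles, 0, 1, 1)
        assert prog2.genotypes[0, 0] == 1
        assert prog2.genotypes[0, 1] == 0

    def test_pooled_genotype_frequencies(self):
        lmap = build_standard_map(1, 1)
        alleles, _ = simulate_lines(lmap, 20000, 29)
        prog = simulate_double_backcross(lmap, alleles, 10000, 10000, 31)
        counts = np.bincount(prog.genotypes[:, 0], minlength=3) / 20000
        for got, want in zip(counts, (0.25, 0.5, 0.25)):
            se = np.sqrt(want * (1 - want) / 20000)
            assert abs(got - want) < 3 * se

    def test_origin_consistency_enforced(self):
        lmap = build_standard_map(1, 1)
        with pytest.raises(ValueError, match="inconsistent"):
            ProgenyData(
                lmap=lmap,
                genotypes=np.array([[0]], dtype=np.int8),
                origin=np.array([0], dtype=np.int8),
            )

    def test_negative_counts_rejected(self):
        lmap = build_standard_map(1, 1)
        alleles, _ = simulate_lines(lmap, 5, 1)
        with pytest.raises(ValueError):
            simulate_double_backcross(lmap, alleles, -1, 2, 1)


class TestPhenotypes:
    def _single_qtl(self, a=2.0, h2=0.5, n_env=1):
        return QtlScenario(
            [QtlEffect("Q", "C1", 25.0, a=a)], [], n_env=n_env, heritability=h2
        )

    def test_degenerate_model_constant(self):
        scen = QtlScenario(
            [QtlEffect("Q", "C1", 25.0)], [], n_env=2, heritability=1.0, mu=3.5
        )
        data = simulate_dataset(scen, 20, 20, 5, lmap=build_standard_map(1, 6))
        assert np.allclose(data.phenotypes["value"], 3.5)

    def test_homozygote_contrast_is_2a(self):
        scen = self._single_qtl(a=1.9, h2=0.999)
        data = simulate_dataset(scen, 4000, 4000, 7, lmap=build_standard_map(1, 6))
        y, env, ind = data.response()
        code = data.qtl_codes[:, 0]
        qq = y[code[ind] == 2].mean()
        qq_ = y[code[ind] == 0].mean()
        assert qq - qq_ == pytest.approx(2 * 1.9, abs=0.05)

    def test_residual_calibration_single_qtl(self):
        # a=2, balanced 1:1, h2=0.5: V_G ~= a^2 * Var(x_A) = 2
        scen = self._single_qtl(a=2.0, h2=0.5)
        data = simulate_dataset(scen, 3000, 3000, 9, lmap=build_standard_map(1, 6))
        s2 = calibrate_residual_variance(scen, data)
        assert s2 == pytest.approx(2.0, rel=0.1)

    def test_calibration_h2_one(self):
        scen = self._single_qtl(h2=1.0)
        data = simulate_dataset(scen, 50, 50, 13, lmap=build_standard_map(1, 6))
        assert calibrate_residual_variance(scen, data) == 0.0

    def test_calibration_no_variance_error(self):
        scen = QtlScenario(
            [QtlEffect("Q", "C1", 25.0)], [], n_env=1, heritability=0.5
        )
        with pytest.raises(ValueError, match="genetic variance"):
            simulate_dataset(scen, 20, 20, 15, lmap=build_standard_map(1, 6))

    def test_calibration_deterministic(self):
        scen = seven_qtl_scenario()
        d1 = simulate_dataset(scen, 100, 100, 21)
        d2 = simulate_dataset(scen, 100, 100, 21)
        assert calibrate_residual_variance(scen, d1) == calibrate_residual_variance(
            scen, d2
        )

    def test_realized_heritability(self):
        scen = seven_qtl_scenario()
        h2 = [
            simulate_dataset(scen, 150, 150, seed).sim_info["realized_h2"]
            for seed in range(12)
        ]
        assert np.mean(h2) == pytest.approx(0.60, abs=0.03)

    def test_variance_decomposition(self):
        scen = seven_qtl_scenario()
        data = simulate_dataset(scen, 150, 150, 3)
        G = genetic_values(data, scen)
        y, env, ind = data.response()
        v_y = y.var()
        v_expected = G.var() + data.sim_info["sigma2_eps"]
        assert v_y == pytest.approx(v_expected, rel=0.15)

    def test_scenario_mismatch_rejected(self):
        # phenotype generation needs the true QTL genotypes of the scenario
        scen = self._single_qtl()
        data = simulate_dataset(scen, 20, 20, 5, lmap=build_standard_map(1, 6))
        other = QtlScenario(
            [QtlEffect("Q", "C1", 35.0, a=1.0)], [], n_env=1, heritability=0.5
        )
        with pytest.raises((ValueError, KeyError, StopIteration)):
            simulate_phenotypes(data, other, 1)


class TestReproducibility:
    def test_identical_seeds_identical_tables(self):
        scen = seven_qtl_scenario()
        d1 = simulate_dataset(scen, 60, 60, 123)
        d2 = simulate_dataset(scen, 60, 60, 123)
        assert np.array_equal(d1.genotypes, d2.genotypes)
        assert d1.phenotypes.equals(d2.phenotypes)

    def test_different_seeds_differ(self):
        scen = seven_qtl_scenario()
        d1 = simulate_dataset(scen, 60, 60, 1)
        d2 = simulate_dataset(scen, 60, 60, 2)
        assert not np.array_equal(d1.genotypes, d2.genotypes)
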