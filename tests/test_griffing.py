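import numpy as np
import pytest

from diallelkit import griffing, synthdata
from diallelkit.phenio import IncompleteDesignError

from conftest import make_table, full_diallel_values


def random_symmetric(p, rng, scale=1.0):
    m = rng.normal(0, scale, size=(p, p))
    return (m + m.T) / 2.0


def ls_oracle_effects(m):
    """Constrained least squares on the half-diallel cells: minimize
    sum_{i<=j} (x_ij - mu - g_i - g_j)^2 subject to sum g = 0, then take
    s as the residual. Solved via the KKT system — independent of the
    closed-form Griffing estimator."""
    p = m.shape[0]
    rows, y = [], []
    for i in range(p):
        for j in range(i, p):
            row = np.zeros(p + 1)
            row[0] = 1.0
            row[1 + i] += 1.0
            row[1 + j] += 1.0
            rows.append(row)
            y.append(m[i, j])
    A, y = np.array(rows), np.array(y)
    C = np.zeros((1, p + 1))
    C[0, 1:] = 1.0
    K = np.block([[A.T @ A, C.T], [C, np.zeros((1, 1))]])
    sol = np.linalg.solve(K, np.concatenate([A.T @ y, [0.0]]))
    mu, g = sol[0], sol[1 : p + 1]
    s = m - mu - g[:, None] - g[None, :]
    return mu, g, s


class TestCellMeans:
    def test_constant_data(self):
        table = make_table(full_diallel_values(4, lambda i, j: 7.0))
        cm = griffing.cell_means(table, "y")
        assert np.all(cm.matrix == 7.0)
        assert cm.grand_total == pytest.approx(7.0 * 10)

    def test_toy_hand_average(self, rng):
        cells = full_diallel_values(3, lambda i, j: float(10 * i + j))
        table = make_table(cells, blocks=2, noise=1.0, rng=rng)
        cm = griffing.cell_means(table, "y")
        sub = table.data
        for (i, j), grp in sub.groupby(["i", "j"]):
            assert cm.matrix[i, j] == pytest.approx(grp["value"].mean())
        assert np.allclose(cm.matrix, cm.matrix.T)

    def test_block_permutation_invariance(self, toy3_table):
        cm1 = griffing.cell_means(toy3_table, "y")
        permuted = toy3_table.data.copy()
        permuted["block"] = permuted["block"].map({1: 2, 2: 1})
        table2 = type(toy3_table)(toy3_table.parents, permuted)
        cm2 = griffing.cell_means(table2, "y")
        assert np.array_equal(cm1.matrix, cm2.matrix)

    def test_missing_cell_raises_with_cells_listed(self, toy3_table):
        toy3_table.data = toy3_table.data.iloc[:-1]
        with pytest.raises(IncompleteDesignError) as err:
            griffing.cell_means(toy3_table, "y")
        assert len(err.value.missing) == 1


class TestRcbdAnova:
    def test_constant_data_zero_ss(self):
        table = make_table(full_diallel_values(3, lambda i, j: 2.5))
        rows = griffing.rcbd_anova(table, "y")
        for src in ("block", "genotype", "error"):
            assert rows[src].ss == pytest.approx(0.0, abs=1e-12)

    def test_toy_against_brute_force_ss(self, rng):
        table = make_table(full_diallel_values(3, lambda i, j: 0.0), blocks=2,
                           noise=2.0, rng=rng)
        rows = griffing.rcbd_anova(table, "y")
        df = table.data
        grand = df["value"].mean()
        geno_means = df.groupby(["i", "j"])["value"].mean()
        block_means = df.groupby("block")["value"].mean()
        ss_geno = 2 * ((geno_means - grand) ** 2).sum()
        ss_block = 6 * ((block_means - grand) ** 2).sum()
        ss_total = ((df["value"] - grand) ** 2).sum()
        assert rows["genotype"].ss == pytest.approx(ss_geno)
        assert rows["block"].ss == pytest.approx(ss_block)
        assert rows["error"].ss == pytest.approx(ss_total - ss_geno - ss_block)

    def test_single_block_rejected(self):
        table = make_table(full_diallel_values(3, lambda i, j: 1.0), blocks=1)
        with pytest.raises(ValueError, match="2 blocks"):
            griffing.rcbd_anova(table, "y")


class TestGriffingPartition:
    def test_constant_data(self):
        table = make_table(full_diallel_values(4, lambda i, j: 3.0))
        cm = griffing.cell_means(table, "y")
        ss_gca, ss_sca = griffing.griffing_partition(cm)
        assert ss_gca == pytest.approx(0.0, abs=1e-10)
        assert ss_sca == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("p", [3, 5, 8])
    def test_partition_identity_random_data(self, p, rng):
        table = make_table(full_diallel_values(p, lambda i, j: 0.0), blocks=3,
                           noise=3.0, rng=rng)
        cm = griffing.cell_means(table, "y")
        ss_gca, ss_sca = griffing.griffing_partition(cm)
        ss_geno = griffing.rcbd_anova(table, "y")["genotype"].ss
        assert ss_gca + ss_sca == pytest.approx(ss_geno, rel=1e-8)
        assert ss_gca >= 0 and ss_sca >= 0

    def test_p2_rejected(self):
        cm = griffing.GenotypeCellMeans(
            "y", __import__("diallelkit").phenio.ParentSet(("A", "B")),
            np.array([[1.0, 2.0], [2.0, 3.0]]), 2,
        )
        with pytest.raises(ValueError):
            griffing.griffing_partition(cm)


class TestEffects:
    def test_constant_data(self):
        table = make_table(full_diallel_values(4, lambda i, j: 5.0))
        ca = griffing.estimate_effects(griffing.cell_means(table, "y"))
        assert ca.mu == pytest.approx(5.0)
        assert np.allclose(ca.gca, 0) and np.allclose(ca.sca, 0)

    @pytest.mark.parametrize("p", [3, 4, 5])
    def test_equals_constrained_ls_oracle(self, p, rng):
        m = random_symmetric(p, rng, scale=2.0)
        mu, g, s = griffing.effects_from_means(m)
        mu_o, g_o, s_o = ls_oracle_effects(m)
        assert mu == pytest.approx(mu_o, rel=1e-10)
        assert np.allclose(g, g_o, atol=1e-10)
        assert np.allclose(s, s_o, atol=1e-10)

    def test_saturation_and_sum_zero(self, sim10_table):
        table, _ = sim10_table
        cm = griffing.cell_means(table, "t1")
        ca = griffing.estimate_effects(cm)
        assert np.allclose(ca.fitted(), cm.matrix, atol=1e-10)
        assert abs(ca.gca.sum()) <= 1e-9 * max(1.0, np.abs(ca.gca).max())

    def test_scale_equivariance(self, sim10_table):
        table, _ = sim10_table
        cm = griffing.cell_means(table, "t1")
        ca = griffing.estimate_effects(cm)
        cm_scaled = griffing.GenotypeCellMeans("t1", cm.parents, cm.matrix * 10, cm.b)
        ca10 = griffing.estimate_effects(cm_scaled)
        assert np.allclose(ca10.gca, 10 * ca.gca)
        assert np.allclose(ca10.sca, 10 * ca.sca)
        ss1 = griffing.griffing_partition(cm)
        ss10 = griffing.griffing_partition(cm_scaled)
        assert ss10[0] == pytest.approx(100 * ss1[0], rel=1e-9)
        assert ss10[1] == pytest.approx(100 * ss1[1], rel=1e-9)


class TestVarianceComponents:
    def test_all_ms_equal_null_case(self):
        vc = griffing.components_from_ms(2.0, 2.0, 2.0, p=10)
        assert vc.sigma2_gca == 0 and vc.sigma2_sca == 0
        assert vc.ratio_component is None and vc.ratio_baker is None
        assert any("undefined" in f for f in vc.flags)

    def test_negative_components_flagged_not_truncated(self):
        vc = griffing.components_from_ms(1.0, 1.5, 2.0, p=10)
        assert vc.sigma2_gca < 0 and vc.sigma2_sca < 0
        assert "negative sigma2_gca" in vc.flags

    def test_heritability_limits(self):
        # pure additive, noiseless: sigma2_sca = sigma2_error = 0
        vc = griffing.components_from_ms(12.0, 0.0, 0.0, p=10)
        assert vc.h2 == pytest.approx(1.0) and vc.H2 == pytest.approx(1.0)
        # no additive variance: h2 = 0, H2 = s2s/(s2s + s2e)
        vc = griffing.components_from_ms(1.0, 3.0, 1.0, p=10)
        assert vc.h2 == 0.0
        assert vc.H2 == pytest.approx(2.0 / 3.0)
        assert vc.h2 <= vc.H2

    def test_ratio_scale_invariance(self):
        vc1 = griffing.components_from_ms(6.0, 3.0, 1.0, p=10)
        vc2 = griffing.components_from_ms(600.0, 300.0, 100.0, p=10)
        assert vc1.ratio_component == pytest.approx(vc2.ratio_component)
        assert vc1.h2 == pytest.approx(vc2.h2)
        assert vc1.H2 == pytest.approx(vc2.H2)


class TestFTestCalibration:
    def test_type_i_error_under_null(self):
        """Pure-noise diallels: GCA and SCA F-tests at alpha=.05 reject ~5%."""
        from scipy import stats as sps

        p, b, n_sim = 6, 3, 2000
        n_g = p * (p + 1) // 2
        df_gca, df_sca, df_err = p - 1, p * (p - 1) // 2, (n_g - 1) * (b - 1)
        crit_gca = sps.f.ppf(0.95, df_gca, df_err)
        crit_sca = sps.f.ppf(0.95, df_sca, df_err)
        rng = np.random.default_rng(2024)
        iu = np.triu_indices(p)
        rej_g = rej_s = 0
        for _ in range(n_sim):
            y = rng.normal(size=(n_g, b))
            parts = griffing.rcbd_ss(y)
            means = y.mean(axis=1)
            m = np.zeros((p, p))
            m[iu] = means
            m = np.triu(m) + np.triu(m, 1).T
            ss_gca, ss_sca = griffing.griffing_ss(m, b)
            ms_e = parts["error"][1] / df_err
            rej_g += (ss_gca / df_gca) / ms_e > crit_gca
            rej_s += (ss_sca / df_sca) / ms_e > crit_sca
        assert abs(rej_g / n_sim - 0.05) <= 0.02
        assert abs(rej_s / n_sim - 0.05) <= 0.02


class TestRecovery:
    def test_component_and_heritability_recovery(self):
        """Known (s2g, s2s, s2e) = (4, 1, 1): estimates unbiased within MC error."""
        p, b, n_sim = 10, 3, 500
        rng = np.random.default_rng(99)
        iu = np.triu_indices(p)
        n_g = len(iu[0])
        df_err = (n_g - 1) * (b - 1)
        est = []
        for _ in range(n_sim):
            y, _ = synthdata.simulate_trait_arrays(p, b, 50.0, 4.0, 1.0, 0.5, 1.0, rng)
            parts = griffing.rcbd_ss(y)
            m = np.zeros((p, p))
            m[iu] = y.mean(axis=1)
            m = np.triu(m) + np.triu(m, 1).T
            ss_gca, ss_sca = griffing.griffing_ss(m, b)
            vc = griffing.components_from_ms(
                ss_gca / (p - 1), ss_sca / (p * (p - 1) // 2),
                parts["error"][1] / df_err, p, b=b,
            )
            est.append((vc.sigma2_gca, vc.sigma2_sca, vc.sigma2_error, vc.h2))
        est = np.array(est)
        mean = est.mean(axis=0)
        sem = est.std(axis=0, ddof=1) / np.sqrt(n_sim)
        true_h2 = 2 * 4 / (2 * 4 + 1 + 1)
        # Method 2 expected mean squares leak sigma2_sca/(p+2) into the GCA
        # component; the recovery targets account for that.
        for k, truth in enumerate([4.0 + 1.0 / (p + 2), 1.0, 1.0]):
            assert abs(mean[k] - truth) <= 4 * sem[k] + 0.02 * truth
        assert abs(mean[3] - true_h2) <= 4 * sem[3] + 0.015


class TestScaPercentAndHeterosis:
    def test_sca_percent_arithmetic_and_zero(self, sim10_table):
        table, _ = sim10_table
        ca = griffing.estimate_effects(griffing.cell_means(table, "t1"))
        ca_zero = griffing.CombiningAbilities("t1", ca.parents, ca.mu,
                                             np.zeros_like(ca.gca), np.zeros_like(ca.sca))
        sp = griffing.sca_percent(ca_zero, table, "t1")
        assert np.allclose(sp["sca_percent"], 0.0)

    def test_sca_percent_simple_ratio(self):
        table = make_table({("A", "A"): 0.0, ("B", "B"): 0.0, ("C", "C"): 0.0,
                            ("A", "B"): 4.0, ("A", "C"): 4.0, ("B", "C"): 4.0})
        ca = griffing.estimate_effects(griffing.cell_means(table, "y"))
        ca.sca = np.ones_like(ca.sca)  # s_ij = 1, hybrid mean = 4 -> 25%
        sp = griffing.sca_percent(ca, table, "y")
        assert np.allclose(sp["sca_percent"], 25.0)

    def test_sca_percent_scale_invariant(self, sim10_table):
        table, _ = sim10_table
        ca = griffing.estimate_effects(griffing.cell_means(table, "t1"))
        sp1 = griffing.sca_percent(ca, table, "t1")
        scaled = table.data.copy()
        scaled["value"] *= 10
        table10 = type(table)(table.parents, scaled)
        ca10 = griffing.estimate_effects(griffing.cell_means(table10, "t1"))
        sp10 = griffing.sca_percent(ca10, table10, "t1")
        assert np.allclose(sp1["sca_percent"], sp10["sca_percent"])

    @pytest.mark.parametrize(
        "f1,expected", [(2.0, 0.0), (3.0, 50.0), (1.0, -50.0)]
    )
    def test_heterosis_formula(self, f1, expected):
        table = make_table({("A", "A"): 1.0, ("B", "B"): 3.0, ("A", "B"): f1})
        het = griffing.heterosis(table, "y")
        assert het.loc[0, "mid_parent"] == pytest.approx(2.0)
        assert het.loc[0, "heterosis"] == pytest.approx(expected)

    def test_heterosis_mp_zero_flagged(self):
        table = make_table({("A", "A"): -1.0, ("B", "B"): 1.0, ("A", "B"): 2.0})
        het = griffing.heterosis(table, "y")
        assert np.isnan(het.loc[0, "heterosis"])
        assert "MP = 0" in het.loc[0, "flag"]

    def test_heterosis_scale_invariant(self, sim10_table):
        table, _ = sim10_table
        h1 = griffing.heterosis(table, "t1")
        scaled = table.data.copy()
        scaled["value"] *= 3.0
        h3 = griffing.heterosis(type(table)(table.parents, scaled), "t1")
        assert np.allclose(h1["heterosis"], h3["heterosis"])


class TestDiallelAnovaTable:
    def test_degrees_of_freedom_and_f_tests(self, sim10_table):
        table, _ = sim10_table
        anova = griffing.diallel_anova(table, "t1")
        assert anova["blocks"].df == 2
        assert anova["genotypes"].df == 54
        assert anova["gca"].df == 9
        assert anova["sca"].df == 45
        assert anova["error"].df == 108
        assert anova["gca"].ss + anova["sca"].ss == pytest.approx(
            anova["genotypes"].ss, rel=1e-8
        )
        for src in ("blocks", "genotypes", "gca", "sca"):
            assert 0 <= anova[src].p_value <= 1
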