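"""RPKM, dispersion, exact test, FDR and responsiveness calls."""

import shutil
import subprocess
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thermotx import (
    ResponsivenessCriteria,
    SimulationConfig,
    bh_fdr,
    compute_rpkm,
    de_comparison,
    estimate_dispersion,
    exact_test_two_group,
    pca_samples,
    simulate_expression_experiment,
    updown_summary,
)
from thermotx.de import call_responsive, de_all_comparisons
from thermotx.errors import DataError


def enumeration_oracle(y1: int, y2: int, n1: int, n2: int, phi: float) -> float:
    """Independent brute-force conditional p-value.

    Enumerates every split of the total with direct pmf products (linear
    scale, no shared code with the implementation's log-space path).
    """
    s = y1 + y2
    lam = s / (n1 + n2)
    if phi == 0:
        probs = np.array(
            [stats.poisson.pmf(k, n1 * lam) * stats.poisson.pmf(s - k, n2 * lam)
             for k in range(s + 1)]
        )
    else:
        r1, r2 = n1 / phi, n2 / phi
        mu1, mu2 = n1 * lam, n2 * lam
        probs = np.array(
            [stats.nbinom.pmf(k, r1, r1 / (r1 + mu1))
             * stats.nbinom.pmf(s - k, r2, r2 / (r2 + mu2))
             for k in range(s + 1)]
        )
    probs = probs / probs.sum()
    return min(1.0, probs[probs <= probs[y1] * (1 + 1e-12)].sum())


class TestRpkm:
    def test_formula_cases(self, tiny_experiment):
        rpkm = compute_rpkm(tiny_experiment)
        # count 0 -> 0
        assert rpkm.loc["g2", "s1"] == 0.0
        # direct formula: 1e9 * c / (len * total)
        total = tiny_experiment.counts["s1"].sum()
        assert rpkm.loc["g1", "s1"] == pytest.approx(1e9 * 1000 / (1000 * total))

    def test_matches_elementwise_oracle(self):
        rng = np.random.default_rng(2)
        exp, _ = simulate_expression_experiment(SimulationConfig(seed=2, n_genes=20))
        rpkm = compute_rpkm(exp)
        counts = exp.counts.to_numpy(dtype=float)
        lengths = exp.genes["length_nt"].to_numpy(dtype=float)
        totals = counts.sum(axis=0)
        for i in range(20):
            for j in range(counts.shape[1]):
                expect = 1e9 * counts[i, j] / (lengths[i] * totals[j])
                assert rpkm.iloc[i, j] == pytest.approx(expect, rel=1e-12)

    def test_scale_invariance_per_sample(self, tiny_experiment):
        """Scaling one sample's counts and total together keeps its RPKM."""
        rpkm1 = compute_rpkm(tiny_experiment)
        exp2 = tiny_experiment
        counts2 = exp2.counts.copy()
        counts2["s1"] = counts2["s1"] * 10
        from thermotx.containers import ExpressionExperiment

        exp2 = ExpressionExperiment(counts2, exp2.samples, exp2.genes)
        rpkm2 = compute_rpkm(exp2)
        pd.testing.assert_series_equal(rpkm1["s1"], rpkm2["s1"])


class TestDispersion:
    def test_poisson_data_near_zero(self):
        rng = np.random.default_rng(10)
        mu = 2.0 ** rng.normal(7, 1.5, 2000)
        counts = rng.poisson(np.repeat(mu[:, None], 4, axis=1))
        assert estimate_dispersion(counts, [0, 0, 1, 1]) < 0.02

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(11)
        mu = 2.0 ** rng.normal(8, 1.5, 2000)
        size = 1 / 0.2
        counts = rng.negative_binomial(
            size, size / (size + np.repeat(mu[:, None], 6, axis=1))
        )
        est = estimate_dispersion(counts, [0, 0, 0, 1, 1, 1])
        assert est == pytest.approx(0.2, rel=0.25)

    def test_identical_counts_give_zero(self):
        counts = np.full((1, 4), 17)
        assert estimate_dispersion(counts, [0, 0, 1, 1]) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(DataError):
            estimate_dispersion(np.zeros((5, 4)), [0, 0, 1, 1])


class TestExactTest:
    def test_symmetric_mode_p_is_one(self):
        assert exact_test_two_group([5], [5], 1, 1, 0.0)[0] == pytest.approx(1.0)

    def test_ten_versus_zero_binomial(self):
        expect = float(2 * Fraction(1, 2) ** 10)
        p = exact_test_two_group([10], [0], 1, 1, 0.0)[0]
        assert p == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    def test_matches_enumeration_oracle(self, phi):
        """All splits of totals up to 30, three dispersions, 1e-10 parity."""
        for s in [1, 2, 5, 9, 17, 30]:
            for y1 in range(s + 1):
                p = exact_test_two_group([y1], [s - y1], 2, 2, phi)[0]
                oracle = enumeration_oracle(y1, s - y1, 2, 2, phi)
                assert p == pytest.approx(oracle, abs=1e-10)

    def test_unequal_group_sizes_match_oracle(self):
        for y1, y2 in [(12, 3), (0, 20), (7, 7)]:
            p = exact_test_two_group([y1], [y2], 3, 2, 0.2)[0]
            assert p == pytest.approx(enumeration_oracle(y1, y2, 3, 2, 0.2), abs=1e-10)

    def test_group_swap_preserves_p(self):
        rng = np.random.default_rng(5)
        y1 = rng.integers(0, 200, 50)
        y2 = rng.integers(0, 200, 50)
        p12 = exact_test_two_group(y1, y2, 2, 2, 0.1)
        p21 = exact_test_two_group(y2, y1, 2, 2, 0.1)
        np.testing.assert_allclose(p12, p21, atol=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            exact_test_two_group([-1], [5], 1, 1, 0.0)

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="Rscript not available")
    def test_matches_edger_small_p_oracle(self, tmp_path):
        """Independent cross-check against edgeR's exactTestBySmallP."""
        rng = np.random.default_rng(42)
        counts = rng.negative_binomial(5, 0.3, size=(60, 4))
        np.savetxt(tmp_path / "counts.tsv", counts, fmt="%d", delimiter="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f"counts <- as.matrix(read.table('{tmp_path}/counts.tsv'))\n"
            "p <- exactTestBySmallP(counts[,1:2], counts[,3:4], dispersion=0.2)\n"
            f"write.table(p, '{tmp_path}/p.tsv', row.names=FALSE, col.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        r_p = np.loadtxt(tmp_path / "p.tsv")
        y1 = counts[:, :2].sum(axis=1)
        y2 = counts[:, 2:].sum(axis=1)
        py_p = exact_test_two_group(y1, y2, 2, 2, 0.2)
        np.testing.assert_allclose(py_p, r_p, atol=1e-8)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.9]), [0.03, 0.03, 0.9])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_fdr([0.2] * 5), [0.2] * 5)

    def test_empty_input(self):
        assert bh_fdr([]).size == 0

    def test_matches_hand_stepup_oracle(self):
        rng = np.random.default_rng(1)
        p = rng.random(200)
        # independent step-up implementation
        order = np.argsort(p)
        n = len(p)
        q = np.empty(n)
        prev = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            prev = min(prev, p[i] * n / rank)
            q[i] = prev
        np.testing.assert_allclose(bh_fdr(p), q, atol=1e-12)
        assert (bh_fdr(p) >= p - 1e-15).all()


class TestResponsiveCalls:
    CRIT = ResponsivenessCriteria()

    @pytest.mark.parametrize(
        "q,fold,reads,expect",
        [
            (0.04, 2.0, 21, True),    # fold boundary is inclusive
            (0.04, 1.9, 1000, False),
            (0.04, 4.0, 20, False),   # reads boundary is strict
            (0.05, 4.0, 100, False),  # FDR boundary is strict
        ],
    )
    def test_criteria_boundaries(self, q, fold, reads, expect):
        flag, _ = call_responsive(q, fold, reads, 10.0, 5.0, self.CRIT)
        assert flag is expect

    def test_direction_from_mean_rpkm(self):
        _, d_up = call_responsive(0.01, 3.0, 100, 30.0, 10.0, self.CRIT)
        _, d_down = call_responsive(0.01, 3.0, 100, 10.0, 30.0, self.CRIT)
        assert (d_up, d_down) == ("up", "down")


class TestComparisons:
    def test_group_swap_inverts_direction(self, default_experiment):
        exp, _ = default_experiment
        fwd = de_comparison(exp, 30.0, 65.0)
        rev = de_comparison(exp, 65.0, 30.0)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)
        changed = fwd["mean_rpkm_test"] != fwd["mean_rpkm_ref"]
        assert (
            fwd.loc[changed, "direction"] != rev.loc[changed, "direction"]
        ).all()

    def test_updown_summary_counts(self):
        tables = {
            30.0: pd.DataFrame(
                {
                    "reference_temperature_C": [65.0] * 3,
                    "direction": ["up", "up", "down"],
                    "responsive": [True, True, True],
                },
                index=["a", "b", "c"],
            )
        }
        summary = updown_summary(tables)
        row = summary[summary["comparison"] == "30v65"].iloc[0]
        assert (row["up"], row["down"]) == (2, 1)
        pooled = summary[summary["comparison"] == "pooled"].iloc[0]
        assert pooled["responsive"] == 3

    def test_no_responsive_gives_zeros(self, small_experiment):
        exp, _ = small_experiment
        tables = de_all_comparisons(exp)
        for tab in tables.values():
            # all-null data: expect (almost) no calls; direction counts consistent
            resp = tab[tab["responsive"]]
            assert len(resp) <= 2

    def test_planted_directions_match_truth(self, default_experiment):
        exp, truth = default_experiment
        tab = de_comparison(exp, 30.0, 65.0)
        planted_up = truth.index[truth["offset_log2_30C"] >= 2]
        called = tab.loc[planted_up]
        called = called[called["responsive"]]
        assert len(called) > 20
        assert (called["direction"] == "up").all()


class TestPca:
    def test_duplicated_sample_identical_coordinates(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        mat["d"] = mat["c"]
        coords, _, frac = pca_samples(mat)
        np.testing.assert_allclose(coords.loc["c"], coords.loc["d"], atol=1e-9)
        assert frac.sum() == pytest.approx(1.0, abs=1e-9)

    def test_three_by_three_matches_eigen_oracle(self):
        mat = pd.DataFrame(
            [[1.0, 2.0, 3.0], [2.0, 1.0, 5.0], [0.5, 0.1, 0.2]],
            columns=["s1", "s2", "s3"],
        )
        coords, _, frac = pca_samples(mat)
        x = mat.to_numpy().T
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc @ xc.T)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0, None)
        expect_frac = evals[: len(frac)] / evals.sum()
        np.testing.assert_allclose(frac, expect_frac, atol=1e-9)
        # coordinates agree up to per-component sign
        proj = xc @ (xc.T @ evecs[:, order])  # not needed; use svd directly
        for j in range(coords.shape[1]):
            col = coords.iloc[:, j].to_numpy()
            assert abs(col @ col) == pytest.approx(evals[j], abs=1e-9)

    def test_constant_matrix_rejected(self):
        mat = pd.DataFrame(np.ones((10, 4)), columns=list("abcd"))
        with pytest.raises(DataError):
            pca_samples(mat)
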