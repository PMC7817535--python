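"""REML engine: AR1 structures, likelihood oracle equivalence, fitting,
heritability, and nesting behaviour."""

import numpy as np
import pandas as pd
import pytest

import treeace as t
from treeace.models import reml_neg2ll
from treeace.pedigree import additive_matrix


def brute_force_neg2ll(y, X, V):
    """-2 REML LL via the explicit projection matrix P (independent route)."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.inv(XtViX) @ X.T @ Vi
    sign, logdet_v = np.linalg.slogdet(V)
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    return float(logdet_v + logdet_x + y @ P @ y + (n - p) * np.log(2 * np.pi))


def random_instance(rng, n):
    """Random y, X and a PSD covariance built from random components."""
    p = rng.integers(1, 3)
    X = np.column_stack([np.ones(n)] +
                        [rng.normal(size=n) for _ in range(p - 1)])
    L = rng.normal(size=(n, n)) * 0.3
    V = L @ L.T + np.diag(rng.uniform(0.5, 2.0, n))
    y = rng.normal(size=n)
    return y, X, V


class TestAR1Structures:
    def test_identity_at_rho_zero(self):
        assert np.allclose(t.ar1_corr(4, 0.0), np.eye(4))

    def test_printed_3x3(self):
        want = np.array([[1, .5, .25], [.5, 1, .5], [.25, .5, 1]])
        assert np.allclose(t.ar1_corr(3, 0.5), want)

    def test_inverse_tridiagonal(self):
        rho = 0.7
        Cinv = np.linalg.inv(t.ar1_corr(6, rho))
        off = -rho / (1 - rho ** 2)
        assert Cinv[2, 3] == pytest.approx(off)
        assert abs(Cinv[0, 2]) < 1e-10  # beyond first off-diagonal: zero

    def test_invalid_rho(self):
        with pytest.raises(ValueError):
            t.ar1_corr(3, 1.0)

    def test_residual_cov_diagonal_when_uncorrelated(self):
        r = t.residual_cov(np.arange(4), np.zeros(4, int), 2.0, 0.0, 0.0, 0.5)
        assert np.allclose(r, np.diag(np.full(4, 2.5)))

    def test_adjacent_columns_entry(self):
        r = t.residual_cov(np.array([0, 0]), np.array([0, 1]),
                           1.5, 0.6, 0.4, 0.0)
        assert r[0, 1] == pytest.approx(1.5 * 0.4)

    def test_subset_equals_full_grid_then_delete(self):
        # gapped 5x5 grid: restriction == build full Kronecker, delete rows
        rng = np.random.default_rng(0)
        rows, cols = np.meshgrid(np.arange(5), np.arange(5), indexing="ij")
        rows, cols = rows.ravel(), cols.ravel()
        keep = np.sort(rng.choice(25, size=20, replace=False))
        sub = t.residual_cov(rows[keep], cols[keep], 1.3, 0.55, -0.35, 0.7)
        full = 1.3 * np.kron(t.ar1_corr(5, 0.55), t.ar1_corr(5, -0.35)) \
            + 0.7 * np.eye(25)
        assert np.max(np.abs(sub - full[np.ix_(keep, keep)])) < 1e-12


class TestREMLLikelihood:
    def test_iid_closed_form(self):
        # y=[1,2,3], intercept, sigma2=1: log 3 + 2 + 2 log 2pi
        y = np.array([1.0, 2.0, 3.0])
        X = np.ones((3, 1))
        got = reml_neg2ll(y, X, np.eye(3))
        want = np.log(3) + 2 + 2 * np.log(2 * np.pi)
        assert got == pytest.approx(want, abs=1e-9)
        assert want == pytest.approx(6.774, abs=5e-3)

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        y, X, V = random_instance(rng, 8)
        shifted = y + 10 * X[:, 0]
        assert reml_neg2ll(shifted, X, V) == pytest.approx(
            reml_neg2ll(y, X, V), abs=1e-8)

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(8):
            y, X, V = random_instance(rng, int(rng.integers(5, 11)))
            assert reml_neg2ll(y, X, V) == pytest.approx(
                brute_force_neg2ll(y, X, V), abs=1e-8)

    def test_nonpd_penalised_not_raised(self, small_trial, small_pedigree,
                                        small_amat):
        _, _, trees = small_trial
        sim = t.SimulationParams()
        res = t.simulate_trait(trees, small_pedigree, sim, 0, spacing=3.2)
        df = trees.copy()
        df["y"] = res["y"]
        model = t.SpatialGeneticModel.from_dataframe(
            df, t.ModelSpec("BA", "y"), small_amat)
        val = model.neg2ll(np.full(len(model.var_names), 40.0))
        assert np.isfinite(val)


@pytest.fixture(scope="module")
def balanced_halfsib():
    """Balanced half-sib families, no spatial structure, on a grid."""
    n_fam, n_off = 60, 8
    ped = t.simulate_pedigree(n_fam, "half_sib", 0, n_offspring=n_off)
    amat = additive_matrix(ped)
    rng = np.random.default_rng(42)
    from treeace.pedigree import gene_drop
    a = gene_drop(ped, 2.0, rng)
    offspring = ped.records[ped.records["sire"] != 0]
    n = len(offspring)
    y = a.loc[offspring["id"]].to_numpy() + rng.normal(0, np.sqrt(2.0), n)
    rows, cols = np.divmod(np.arange(n), 24)
    idx = np.arange(n)
    data = pd.DataFrame({
        "tree_id": offspring["id"].to_numpy(),
        "y": y, "control": False,
        # blocking orthogonal to families: rep = offspring index within
        # family, iblocks cut across families
        "rep": idx % n_off,
        "iblock": (idx // n_off) % 3,
        "row": rows, "col": cols,
    })
    return data, amat, ped


class TestFit:
    def test_balanced_halfsib_matches_anova(self, balanced_halfsib):
        # sigma2_a ~= 4 x the one-way ANOVA family variance component
        data, amat, ped = balanced_halfsib
        fam = ped.records.set_index("id")["sire"].loc[data["tree_id"]].to_numpy()
        df = pd.DataFrame({"fam": fam, "y": data["y"]})
        n_off = df.groupby("fam").size().iloc[0]
        ms_b = n_off * df.groupby("fam")["y"].mean().var(ddof=1)
        ms_w = df.groupby("fam")["y"].var(ddof=1).mean()
        anova_fam = (ms_b - ms_w) / n_off

        fit = t.SpatialGeneticModel.from_dataframe(
            data, t.ModelSpec("B", "y"), amat).fit(seed=0)
        assert fit.converged
        assert fit.params["sigma2_a"] == pytest.approx(4 * anova_fam, rel=0.12)

    def test_reproducible_to_last_bit(self, balanced_halfsib):
        data, amat, _ = balanced_halfsib
        spec = t.ModelSpec("B", "y")
        f1 = t.SpatialGeneticModel.from_dataframe(data, spec, amat).fit(seed=3)
        f2 = t.SpatialGeneticModel.from_dataframe(data, spec, amat).fit(seed=3)
        assert f1.n2ll == f2.n2ll
        assert f1.params == f2.params

    def test_spatial_recovery_single_dataset(self, small_trial,
                                             small_pedigree, small_amat):
        # one 432-tree dataset: estimates within 3 SE of the truth
        _, _, trees = small_trial
        sim = t.SimulationParams(mu=10, sigma2_a=1.0, sigma2_xi=1.0,
                                 sigma2_eta=1.0, rho_row=0.6, rho_col=0.6)
        res = t.simulate_trait(trees, small_pedigree, sim, 17, spacing=3.2)
        df = trees.copy()
        df["y"] = res["y"]
        fit = t.SpatialGeneticModel.from_dataframe(
            df, t.ModelSpec("BA", "y"), small_amat).fit(seed=0)
        assert fit.converged
        truth = {"sigma2_a": 1.0, "sigma2_xi": 1.0, "rho_row": 0.6,
                 "rho_col": 0.6, "sigma2_eta": 1.0}
        for k, v in truth.items():
            assert abs(fit.params[k] - v) < 3 * fit.bse[k] + 0.05, k

    def test_null_genetic_variance(self, small_trial, small_pedigree,
                                   small_amat):
        # sigma2_a = 0 truth: h2 near zero
        _, _, trees = small_trial
        sim = t.SimulationParams(sigma2_a=0.0, sigma2_eta=1.0)
        res = t.simulate_trait(trees, small_pedigree, sim, 23, spacing=3.2)
        df = trees.copy()
        df["y"] = res["y"]
        fit = t.SpatialGeneticModel.from_dataframe(
            df, t.ModelSpec("B", "y"), small_amat).fit(seed=0)
        assert fit.h2 < 0.15

    def test_rank_deficient_design_rejected(self, small_amat):
        y = np.ones(4)
        X = np.ones((4, 2))
        with pytest.raises(ValueError, match="rank"):
            t.SpatialGeneticModel(y, X, t.ModelSpec("B", "y"),
                                  amat=np.eye(4),
                                  rep_codes=np.zeros(4),
                                  iblock_codes=np.zeros(4))


class TestHeritability:
    def test_ratio_rule(self, balanced_halfsib):
        data, amat, _ = balanced_halfsib
        fit = t.SpatialGeneticModel.from_dataframe(
            data, t.ModelSpec("B", "y"), amat).fit(seed=0)
        h2, se = fit.heritability()
        va, ve = fit.params["sigma2_a"], fit.params["sigma2_e"]
        assert h2 == pytest.approx(va / (va + ve))
        assert se > 0

    def test_spatial_component_excluded(self, small_trial, small_pedigree,
                                        small_amat):
        _, _, trees = small_trial
        sim = t.SimulationParams(mu=5, sigma2_a=0.4, sigma2_xi=1.0,
                                 sigma2_eta=0.6, rho_row=0.5, rho_col=0.5)
        res = t.simulate_trait(trees, small_pedigree, sim, 5, spacing=3.2)
        df = trees.copy()
        df["y"] = res["y"]
        fit = t.SpatialGeneticModel.from_dataframe(
            df, t.ModelSpec("BA", "y"), small_amat).fit(seed=0)
        va, ve = fit.params["sigma2_a"], fit.params["sigma2_eta"]
        # denominator uses the units component only, not sigma2_xi
        assert fit.h2 == pytest.approx(va / (va + ve))

    def test_jackknife_se_same_order(self, balanced_halfsib):
        # delta-method SE comparable to a family-jackknife SE
        data, amat, ped = balanced_halfsib
        fit = t.SpatialGeneticModel.from_dataframe(
            data, t.ModelSpec("B", "y"), amat).fit(seed=0)
        h2, se = fit.heritability()
        fam = ped.records.set_index("id")["sire"].loc[data["tree_id"]].to_numpy()
        fams = np.unique(fam)
        rng = np.random.default_rng(0)
        pseudo = []
        for f in rng.choice(fams, size=12, replace=False):
            sub = data[fam != f].reset_index(drop=True)
            fsub = t.SpatialGeneticModel.from_dataframe(
                sub, t.ModelSpec("B", "y"), amat).fit(seed=0)
            pseudo.append(fsub.h2)
        # delete-one jackknife variance scaled to the full family count
        jk = np.sqrt((len(fams) - 1) * np.var(pseudo, ddof=0)
                     * (len(fams) / len(pseudo)) / len(fams))
        assert 0.3 * jk < se < 3.0 * jk

    def test_summary_renders(self, balanced_halfsib):
        data, amat, _ = balanced_halfsib
        fit = t.SpatialGeneticModel.from_dataframe(
            data, t.ModelSpec("B", "y"), amat).fit(seed=0)
        s = fit.summary()
        assert "sigma2_a" in s and "h2" in s and "logLik" in s


class TestNesting:
    def test_larger_family_not_worse(self, small_trial, small_pedigree,
                                     small_amat):
        # on spatially structured data BA >= B and BAC >= BC in LL
        _, _, trees = small_trial
        sim = t.SimulationParams(mu=8, sigma2_a=0.8, sigma2_xi=1.0,
                                 sigma2_eta=0.8, rho_row=0.6, rho_col=0.6,
                                 beta_c=-0.3)
        res = t.simulate_trait(trees, small_pedigree, sim, 31, spacing=3.2)
        df = trees.copy()
        df["y"] = res["y"]
        df["ci"] = res["true_ci"]
        fits = {}
        for fam in ("B", "BA", "BC", "BAC"):
            comp = "CI" if fam in ("BC", "BAC") else None
            spec = t.ModelSpec(fam, "y", comp, competition_random=bool(comp))
            fits[fam] = t.SpatialGeneticModel.from_dataframe(
                df, spec, small_amat, comp_col="ci").fit(seed=0)
        assert fits["BA"].llf >= fits["B"].llf - 1e-4
        assert fits["BAC"].llf >= fits["BC"].llf - 1e-4
        assert fits["BC"].llf >= fits["B"].llf - 1e-4
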