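"""Simulation studies over the full workflow: parameter recovery of the
ACE (BAC) model, model-family ranking, and type-I error control.

These are the package's calibration experiments: each study simulates
trials with known truth, runs the fitting workflow, and summarises how
well the truth is recovered. Problem sizes are configurable; the defaults
trade Monte-Carlo precision against runtime (a 24-block trial of 864
trees for recovery, a 12-block trial of 432 trees for the ranking and
null studies).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .evaluate import likelihood_ratio
from .models import ModelSpec, SpatialGeneticModel
from .pedigree import Pedigree, additive_matrix, simulate_pedigree
from .simulate import SimulationParams, simulate_trait
from .trial import TrialDesignParams, apply_mortality, assign_families, generate_layout

__all__ = ["recovery_study", "ranking_study", "type1_study",
           "RECOVERY_TRUTH", "make_trial"]

#: truth used by the calibration studies: unit genetic, spatial and nugget
#: variances, moderate autocorrelation, a -0.3 standardized competition
#: effect, 10% mortality.
RECOVERY_TRUTH = SimulationParams(mu=10.0, control_effect=0.5, sigma2_a=1.0,
                                  sigma2_xi=1.0, sigma2_eta=1.0,
                                  rho_row=0.6, rho_col=0.6, beta_c=-0.3,
                                  mortality_rate=0.1)

_COMPONENTS = ("sigma2_a", "sigma2_xi", "rho_row", "rho_col", "sigma2_eta")


@dataclass
class Trial:
    params: TrialDesignParams
    trees: pd.DataFrame
    pedigree: Pedigree
    amat: pd.DataFrame


def make_trial(n_replicates: int, arrangement: tuple[int, int],
               seed: int = 11) -> Trial:
    """Trial skeleton (layout, families, pedigree, relationship matrix)."""
    params = TrialDesignParams(n_replicates=n_replicates,
                               replicate_arrangement=arrangement)
    layout = generate_layout(params)
    trees = assign_families(layout, params, seed=seed)
    groups = [trees.loc[trees["family"] == f, "tree_id"].tolist()
              for f in range(1, params.n_families + 1)]
    ped = simulate_pedigree(params.n_families, "half_sib", seed,
                            offspring_ids=groups)
    return Trial(params, trees, ped, additive_matrix(ped))


def _simulate_dataset(trial: Trial, sim: SimulationParams, seed: int
                      ) -> pd.DataFrame:
    trees = apply_mortality(trial.trees, sim.mortality_rate, seed)
    res = simulate_trait(trees, trial.pedigree, sim, seed + 1,
                         spacing=trial.params.spacing)
    df = trees.copy()
    df["y"] = res["y"].to_numpy()
    df["ci"] = res["true_ci"].to_numpy()
    return df


def recovery_study(n_sims: int = 20, n_replicates: int = 8,
                   arrangement: tuple[int, int] = (2, 4),
                   sim: SimulationParams = RECOVERY_TRUTH,
                   seed: int = 0) -> dict:
    """Fit the ACE (BAC) and base (B) models to ``n_sims`` simulated
    trials and measure component recovery.

    Returns per-component mean estimates and percent biases, the pooled
    +-2 SE coverage over the five BAC variance parameters, the fitted
    competition coefficients, and the paired h2 comparison between the
    BAC and B fits (ignoring spatial structure shifts h2).
    """
    trial = make_trial(n_replicates, arrangement)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_sims)
    truth = {k: getattr(sim, k) for k in _COMPONENTS}

    est, ses, betas, h2_bac, h2_b = [], [], [], [], []
    for s in seeds:
        df = _simulate_dataset(trial, sim, int(s))
        bac = SpatialGeneticModel.from_dataframe(
            df, ModelSpec("BAC", "y", "trueCI"), trial.amat,
            comp_col="ci").fit(seed=0)
        b = SpatialGeneticModel.from_dataframe(
            df, ModelSpec("B", "y"), trial.amat).fit(seed=0, compute_se=False)
        est.append([bac.params[k] for k in _COMPONENTS])
        ses.append([bac.bse[k] for k in _COMPONENTS])
        betas.append(bac.fe_params["beta[trueCI]"])
        h2_bac.append(bac.h2)
        h2_b.append(b.h2)
    est = np.asarray(est)
    ses = np.asarray(ses)
    tru = np.array([truth[k] for k in _COMPONENTS])
    bias_pct = 100.0 * (est.mean(axis=0) - tru) / np.abs(tru)
    cover = np.abs(est - tru) <= 2 * ses
    h2_diff = np.asarray(h2_bac) - np.asarray(h2_b)
    tstat, pval = stats.ttest_1samp(h2_diff, 0.0)
    return {
        "components": list(_COMPONENTS),
        "truth": tru.tolist(),
        "mean_estimates": est.mean(axis=0).tolist(),
        "bias_pct": bias_pct.tolist(),
        "max_abs_bias_pct": float(np.max(np.abs(bias_pct))),
        "coverage_pooled": float(np.nanmean(cover)),
        "beta_c_mean": float(np.mean(betas)),
        "beta_c_bias_pct": float(100.0 * (np.mean(betas) - sim.beta_c)
                                 / abs(sim.beta_c)),
        "h2_bac_mean": float(np.mean(h2_bac)),
        "h2_b_mean": float(np.mean(h2_b)),
        "h2_diff_mean": float(h2_diff.mean()),
        "h2_diff_t": float(tstat),
        "h2_diff_p": float(pval),
        "n_sims": n_sims,
        "n_trees": len(trial.trees),
    }


def ranking_study(n_seeds: int = 10, n_replicates: int = 4,
                  arrangement: tuple[int, int] = (2, 2),
                  sim: SimulationParams = RECOVERY_TRUTH,
                  seed: int = 0) -> dict:
    """Fit all four model families to competition + site simulations and
    measure how often the log-likelihood ranking puts BAC first and B
    last (BAC > {BC, BA} > B).

    The competition term is fitted as a one-column random regression so
    all four families share the same fixed effects and their REML
    log-likelihoods are comparable.
    """
    trial = make_trial(n_replicates, arrangement)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_seeds)
    hits, lls = [], []
    for s in seeds:
        df = _simulate_dataset(trial, sim, int(s))
        ll = {}
        for fam in ("B", "BA", "BC", "BAC"):
            comp = "trueCI" if fam in ("BC", "BAC") else None
            spec = ModelSpec(fam, "y", comp, competition_random=bool(comp))
            fit = SpatialGeneticModel.from_dataframe(
                df, spec, trial.amat, comp_col="ci").fit(seed=0,
                                                         compute_se=False)
            ll[fam] = fit.llf
        lls.append(ll)
        hits.append(ll["BAC"] > max(ll["BA"], ll["BC"])
                    and min(ll["BA"], ll["BC"]) > ll["B"])
    return {
        "proportion_expected_order": float(np.mean(hits)),
        "n_seeds": n_seeds,
        "lls": lls,
    }


def type1_study(n_sims: int = 20, n_replicates: int = 8,
                arrangement: tuple[int, int] = (2, 4),
                seed: int = 0, alpha: float = 0.05) -> dict:
    """Null workflow check: no spatial signal, no competition.

    Simulates sigma2_a = 1, sigma2_eta = 2 with all spatial, competition
    and design variances zero, so the B and BA families tie in
    expectation, and counts how often the AR1 term is declared
    significant at ``alpha`` by the boundary-mixture LRT. The default
    24-block scale matches the recovery study; on much smaller grids the
    boundary LRT is anti-conservative (the unidentified AR1 correlations
    have more room to chase noise patterns relative to the information
    in the grid).
    """
    null = SimulationParams(mu=10.0, control_effect=0.5, sigma2_a=1.0,
                            sigma2_eta=2.0, mortality_rate=0.1)
    trial = make_trial(n_replicates, arrangement)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2 ** 31 - 1, size=n_sims)
    pvals = []
    for s in seeds:
        df = _simulate_dataset(trial, null, int(s))
        b = SpatialGeneticModel.from_dataframe(
            df, ModelSpec("B", "y"), trial.amat).fit(seed=0, compute_se=False)
        ba = SpatialGeneticModel.from_dataframe(
            df, ModelSpec("BA", "y"), trial.amat).fit(seed=0,
                                                      compute_se=False)
        _, p = likelihood_ratio(ba, b)
        pvals.append(p)
    pvals = np.asarray(pvals)
    return {
        "rejection_rate": float(np.mean(pvals < alpha)),
        "pvals": pvals.tolist(),
        "n_sims": n_sims,
    }
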