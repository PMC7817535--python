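"""Model comparison and reporting.

Comparisons follow the standard REML workflow: a likelihood-ratio
statistic D = 2(LL_M - LL_B) against the base model, with p-values from
the boundary chi-square mixture (50:50 mass at zero and chi2_q, equal
weights over components for q > 1 extra variance parameters); AIC/BIC;
and two percentage improvements relative to the base model, the change in
narrow-sense heritability and in the independent residual variance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .models import REMLResults

__all__ = [
    "likelihood_ratio",
    "information_criteria",
    "improvement",
    "correlate",
    "build_study_plan",
    "rank_and_report",
    "StudyPlan",
    "FitRecord",
]

#: which model families nest which (AR1 + units treated as an expansion
#: of the iid residual; competition as an added term)
_NESTS = {"B": set(), "BA": {"B"}, "BC": {"B"}, "BAC": {"B", "BA", "BC"}}


def likelihood_ratio(fit_m: REMLResults, fit_b: REMLResults,
                     q: Optional[int] = None) -> tuple[float, float]:
    """LRT statistic D = 2(LL_M - LL_B) and boundary-mixture p-value.

    Requires identical fixed effects (REML likelihoods are otherwise not
    comparable) and a nested family pair. ``q`` defaults to the number of
    variance parameters present in the test model but not the base model
    (the iid residual and the units/nugget play the same role and are not
    counted; correlations unidentified at the boundary are counted, which
    keeps the test honest when a spatial term is added). The p-value uses
    the equal-weight mixture over chi2_0..chi2_q. A negative D (optimizer
    artifact) is reported with a warning and p = 1.
    """
    for f in (fit_m, fit_b):
        if not f.converged:
            raise ValueError("likelihood_ratio requires converged fits")
    if fit_m.fe_params.index.tolist() != fit_b.fe_params.index.tolist():
        raise ValueError("models have different fixed effects; "
                         "REML likelihoods are not comparable")
    if fit_b.model.spec.family not in _NESTS[fit_m.model.spec.family]:
        raise ValueError(
            f"{fit_b.model.spec.family} is not nested in {fit_m.model.spec.family}")
    d = 2.0 * (fit_m.llf - fit_b.llf)
    if q is None:
        def roles(fit):
            return {"residual" if n in ("sigma2_e", "sigma2_eta") else n
                    for n in fit.params}
        q = len(roles(fit_m) - roles(fit_b))
    q = max(int(q), 1)
    if d <= 0:
        if d < 0:
            warnings.warn(f"negative LRT statistic D = {d:.4g} "
                          "(optimizer artifact)")
        return float(d), 1.0
    # equal-weight mixture over chi2_0, chi2_1, ..., chi2_q
    weights = np.full(q + 1, 1.0 / (q + 1))
    p = float(sum(w * (stats.chi2.sf(d, df) if df > 0 else 0.0)
                  for df, w in enumerate(weights)))
    return float(d), p


def information_criteria(fit: REMLResults,
                         bic_convention: str = "printed") -> tuple[float, float]:
    """AIC = -2LL + 2t and BIC with natural-log nu penalty.

    ``bic_convention``: 'printed' uses -2LL + 2 t log(nu); 'standard'
    uses -2LL + t log(nu).
    """
    if not fit.converged:
        raise ValueError("information criteria require a converged fit")
    t, nu = fit.t_params, fit.df_resid
    if nu <= 0:
        raise ValueError("nu = n - p must be positive")
    aic = fit.n2ll + 2.0 * t
    if bic_convention == "printed":
        bic = fit.n2ll + 2.0 * t * np.log(nu)
    elif bic_convention == "standard":
        bic = fit.n2ll + t * np.log(nu)
    else:
        raise ValueError("bic_convention must be 'printed' or 'standard'")
    return float(aic), float(bic)


def improvement(h2_m, h2_b, eps_m: float = np.nan, eps_b: float = np.nan
                ) -> tuple[float, float]:
    """Percentage improvements of a spatial model over the base model.

    Delta-h2% = 100 (h2_M - h2_B) / h2_B and Delta-eps% analogously for
    the independent residual variance. Accepts either two fit results or
    the four scalars (h2 and residual for test and base model).
    """
    if isinstance(h2_m, REMLResults):
        fit_m, fit_b = h2_m, h2_b
        h2_m = fit_m.heritability()[0]
        h2_b = fit_b.heritability()[0]
        eps_m = fit_m.residual_variance
        eps_b = fit_b.residual_variance
    if h2_b == 0 or eps_b == 0:
        raise ZeroDivisionError("base-model h2 and residual must be non-zero")
    return (100.0 * (h2_m - h2_b) / h2_b, 100.0 * (eps_m - eps_b) / eps_b)


def correlate(x, y) -> float:
    """Pearson r with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        raise ValueError("zero variance in one of the columns")
    return float(stats.pearsonr(x[ok], y[ok])[0])


@dataclass
class StudyPlan:
    """The factorial model-run plan: B and BA once per trait, BC and BAC
    once per trait per competition spec.

    ``runs`` lists every individual model fit. ``n_runs`` counts study
    runs the way trial reports conventionally tally them: one run per
    base fit (B, BA) plus one run per trait x competition-metric
    evaluation, within which the BC/BAC pair is fitted and compared —
    2|traits| + |traits||specs| (280 for 5 traits and 54 metrics).
    """

    runs: pd.DataFrame  # columns: trait, family, competition
    n_traits: int = 0
    n_specs: int = 0

    def __len__(self) -> int:
        return len(self.runs)

    @property
    def n_runs(self) -> int:
        return 2 * self.n_traits + self.n_traits * self.n_specs

    def counts(self) -> pd.Series:
        return self.runs["family"].value_counts()


def build_study_plan(traits: Sequence[str],
                     spec_labels: Sequence[str]) -> StudyPlan:
    """Factorial plan; fit rows in deterministic order."""
    if not traits:
        raise ValueError("traits must be non-empty")
    rows = []
    for t in traits:
        rows.append((t, "B", None))
        rows.append((t, "BA", None))
    for t, s in itertools.product(traits, spec_labels):
        rows.append((t, "BC", s))
        rows.append((t, "BAC", s))
    df = pd.DataFrame(rows, columns=["trait", "family", "competition"])
    df = df.drop_duplicates().reset_index(drop=True)
    return StudyPlan(runs=df, n_traits=len(set(traits)),
                     n_specs=len(set(spec_labels)))


class FitRecord:
    """Stand-in for :class:`REMLResults` rebuilt from a serialized fit.

    Carries exactly the surface the comparison and reporting functions
    need, so the evaluation stage can run from fit JSON records without
    refitting.
    """

    class _Spec:
        def __init__(self, family, trait, competition):
            self.family = family
            self.trait = trait
            self.competition = competition

    class _Model:
        def __init__(self, spec):
            self.spec = spec

    def __init__(self, d: dict) -> None:
        self._d = d
        self.model = self._Model(self._Spec(d["family"], d["trait"],
                                            d.get("competition")))
        self.fe_params = pd.Series(d["fe_params"])
        self.converged = bool(d["converged"])
        self.params = d.get("params", {})

    @property
    def llf(self) -> float:
        return float(self._d["llf"])

    @property
    def n2ll(self) -> float:
        return -2.0 * self.llf

    @property
    def t_params(self) -> int:
        return int(self._d["t"])

    @property
    def df_resid(self) -> int:
        return int(self._d["nu"])

    @property
    def residual_variance(self) -> float:
        key = "sigma2_eta" if self.model.spec.family in ("BA", "BAC") else "sigma2_e"
        return float(self.params[key])

    def heritability(self) -> tuple[float, float]:
        return float(self._d["h2"]), float(self._d["h2_se"])


def _result_row(fit: REMLResults, base: Optional[REMLResults],
                bic_convention: str) -> dict:
    h2, h2_se = fit.heritability()
    row = {
        "trait": fit.model.spec.trait,
        "family": fit.model.spec.family,
        "competition": fit.model.spec.competition,
        "LL": fit.llf, "t": fit.t_params, "nu": fit.df_resid,
        "h2": h2, "h2_se": h2_se, "resid": fit.residual_variance,
    }
    aic, bic = information_criteria(fit, bic_convention)
    row["AIC"], row["BIC"] = aic, bic
    if base is None or fit is base:
        row.update(D=0.0, p=1.0, dh2_pct=0.0, deps_pct=0.0)
    else:
        d, p = likelihood_ratio(fit, base)
        dh2, deps = improvement(h2, base.heritability()[0],
                                fit.residual_variance, base.residual_variance)
        row.update(D=d, p=p, dh2_pct=dh2, deps_pct=deps)
    return row


def rank_and_report(fits: Sequence[REMLResults], *,
                    bic_convention: str = "printed",
                    ci_table: Optional[pd.DataFrame] = None,
                    phenotypes: Optional[pd.DataFrame] = None
                    ) -> dict[str, pd.DataFrame]:
    """Build the two report tables from a collection of fits.

    ``model_table``: per trait, every family ranked by decreasing LL (for
    BC/BAC the best competition spec by LL) with D, p, AIC, BIC, h2 +- SE
    and the percentage improvements over the base model. ``best_table``:
    per trait the best competition-bearing model with its crown metric,
    formulation, neighbourhood and, when ``ci_table``/``phenotypes`` are
    given, the Pearson correlation between that index and the trait.
    Non-converged fits are dropped with a warning.
    """
    usable = []
    for f in fits:
        if f.converged:
            usable.append(f)
        else:
            warnings.warn(f"dropping non-converged fit {f.model.spec}")
    rows = []
    best_rows = []
    traits = sorted({f.model.spec.trait for f in usable})
    for trait in traits:
        tf = [f for f in usable if f.model.spec.trait == trait]
        base = next((f for f in tf if f.model.spec.family == "B"), None)
        if base is None:
            warnings.warn(f"trait {trait}: no converged base model; omitted")
            continue
        chosen = []
        for fam in ("B", "BA", "BC", "BAC"):
            cand = [f for f in tf if f.model.spec.family == fam]
            if cand:
                chosen.append(max(cand, key=lambda f: f.llf))
        for f in chosen:
            rows.append(_result_row(f, base, bic_convention))
        comp_fits = [f for f in chosen if f.model.spec.family in ("BC", "BAC")]
        if comp_fits:
            bf = max(comp_fits, key=lambda f: f.llf)
            label = bf.model.spec.competition
            metric, formulation, nb = label.rsplit("_", 2)
            brow = {"trait": trait, "family": bf.model.spec.family,
                    "competition": label, "crown_metric": metric,
                    "formulation": formulation, "neighborhood": nb,
                    "LL": bf.llf}
            if ci_table is not None and phenotypes is not None:
                merged = phenotypes.merge(ci_table, on="tree_id", how="inner")
                col = f"ci_{label}"
                if col in merged.columns:
                    brow["r"] = correlate(merged[col], merged[trait])
            best_rows.append(brow)
    model_table = pd.DataFrame(rows)
    if len(model_table):
        model_table = (model_table
                       .sort_values(["trait", "LL"], ascending=[True, False])
                       .reset_index(drop=True))
        model_table["rank"] = model_table.groupby("trait")["LL"] \
            .rank(ascending=False, method="first").astype(int)
    return {"model_table": model_table, "best_table": pd.DataFrame(best_rows)}
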