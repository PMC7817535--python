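"""REML individual-tree mixed models with pedigree, design and spatial terms.

Four nested model families are supported, differing in how spatial
variation is handled around the shared genetic core y = Xb + Zu + e:

========  ==============  ================================================
family    fixed terms     random / residual terms
========  ==============  ================================================
B         mean + control  pedigree + replicate + iblock:rep + iid residual
BA        mean + control  pedigree + units (nugget) + AR1xAR1 residual
BC        B terms         B + competition covariate
BAC       BA terms        BA + competition covariate
========  ==============  ================================================

The AR1xAR1 residual is the separable field with correlation
rho_row^|dr| * rho_col^|dc| in planting-grid steps; observations with
missing phenotypes are dropped from y while their grid cells remain in
the index set (equivalent to completing the grid with missing values).
The competition covariate is the standardized index, fitted as a fixed
regression by default or as a one-column random regression with its own
variance (``competition_random=True``).

Estimation is REML: -2LL = log|V| + log|X'V^-1 X| + y'Py + (n-p) log 2pi,
maximised over log-variances and atanh-correlations by Nelder-Mead with a
quasi-Newton refinement; standard errors come from the numerical Hessian
at the optimum mapped back by the delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "SpatialGeneticModel",
    "REMLResults",
    "ar1_corr",
    "residual_cov",
    "reml_neg2ll",
    "heritability",
]

MODEL_FAMILIES = ("B", "BA", "BC", "BAC")
_BIG = 1e10
_RHO_BOUND = 0.999


def ar1_corr(n: int, rho: float) -> np.ndarray:
    """AR1 correlation matrix C[i, j] = rho^|i-j|."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    idx = np.arange(n)
    return float(rho) ** np.abs(np.subtract.outer(idx, idx))


def residual_cov(rows: np.ndarray, cols: np.ndarray, sigma2_xi: float,
                 rho_row: float, rho_col: float, sigma2_eta: float) -> np.ndarray:
    """Separable AR1xAR1 + nugget covariance over the observed cells.

    Equivalent to building the full-grid Kronecker matrix
    sigma2_xi * C_rows kron C_cols + sigma2_eta * I and deleting the
    rows/columns of unobserved cells.
    """
    rows = np.asarray(rows, dtype=int)
    cols = np.asarray(cols, dtype=int)
    if len(rows) != len(cols):
        raise ValueError("rows and cols must align")
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    r = sigma2_xi * (float(rho_row) ** dr) * (float(rho_col) ** dc)
    r[np.diag_indices_from(r)] += sigma2_eta
    return r


def reml_neg2ll(y: np.ndarray, X: np.ndarray, V: np.ndarray,
                overwrite_v: bool = False) -> float:
    """-2 REML log-likelihood for a fully-built covariance matrix.

    -2LL = log|V| + log|X'V^-1 X| + y'Py + (n - p) log 2pi, evaluated via
    Cholesky factorisations. Invariant to translating y along columns of X.
    """
    n, p = X.shape
    c, low = linalg.cho_factor(V, lower=True, check_finite=False,
                               overwrite_a=overwrite_v)
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    xy = np.column_stack([X, y])
    vi_xy = linalg.cho_solve((c, low), xy, check_finite=False)
    vi_x, vi_y = vi_xy[:, :p], vi_xy[:, p]
    xtvix = X.T @ vi_x
    cx = linalg.cho_factor(xtvix, lower=True, check_finite=False)
    logdet_x = 2.0 * np.log(np.diag(cx[0])).sum()
    xtviy = X.T @ vi_y
    beta = linalg.cho_solve(cx, xtviy, check_finite=False)
    ypy = float(y @ vi_y - xtviy @ beta)
    return float(logdet_v + logdet_x + ypy + (n - p) * np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one model run."""

    family: str
    trait: str
    competition: Optional[str] = None
    competition_random: bool = False

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"family must be one of {MODEL_FAMILIES}")
        if self.family in ("BC", "BAC") and self.competition is None:
            raise ValueError(f"{self.family} requires a competition spec label")
        if self.family in ("B", "BA") and self.competition is not None:
            raise ValueError(f"{self.family} takes no competition term")

    @property
    def spatial(self) -> bool:
        return self.family in ("BA", "BAC")

    @property
    def has_competition(self) -> bool:
        return self.family in ("BC", "BAC")

    def variance_names(self) -> list[str]:
        names = ["sigma2_a"]
        if self.spatial:
            names += ["sigma2_xi", "rho_row", "rho_col", "sigma2_eta"]
        else:
            names += ["sigma2_rep", "sigma2_iblock", "sigma2_e"]
        if self.has_competition and self.competition_random:
            names.append("sigma2_comp")
        return names


#: alias used in result containers
VarianceComponents = dict


class SpatialGeneticModel:
    """Individual-tree REML mixed model (statsmodels-style).

    Build with :meth:`from_dataframe` and call :meth:`fit`; the result is
    a :class:`REMLResults` carrying variance components with standard
    errors, fixed effects, the REML log-likelihood and heritability.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, spec: ModelSpec, *,
                 amat: Optional[np.ndarray] = None,
                 rep_codes: Optional[np.ndarray] = None,
                 iblock_codes: Optional[np.ndarray] = None,
                 grid_rows: Optional[np.ndarray] = None,
                 grid_cols: Optional[np.ndarray] = None,
                 comp: Optional[np.ndarray] = None,
                 fe_names: Optional[Sequence[str]] = None) -> None:
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.spec = spec
        self.nobs, self.k_fe = self.X.shape
        if np.linalg.matrix_rank(self.X) < self.k_fe:
            raise ValueError("fixed-effect design matrix is rank deficient")
        self.fe_names = list(fe_names) if fe_names else \
            [f"x{i}" for i in range(self.k_fe)]
        if amat is None:
            raise ValueError("an additive relationship matrix is required")
        self.amat = np.asarray(amat, dtype=float)
        self.var_names = spec.variance_names()

        n = self.nobs
        if spec.spatial:
            if grid_rows is None or grid_cols is None:
                raise ValueError("spatial models need grid row/col indices")
            rc = np.column_stack([grid_rows, grid_cols])
            if len(np.unique(rc, axis=0)) != n:
                raise ValueError("grid (row, col) indices must be unique")
            self._dr = np.abs(np.subtract.outer(grid_rows, grid_rows)).astype(int)
            self._dc = np.abs(np.subtract.outer(grid_cols, grid_cols)).astype(int)
        else:
            if rep_codes is None or iblock_codes is None:
                raise ValueError("non-spatial models need rep and iblock codes")
            rep_codes = np.asarray(rep_codes)
            ib = np.asarray(iblock_codes)
            self._m_rep = (rep_codes[:, None] == rep_codes[None, :]).astype(float)
            combo = pd.factorize(pd.Series(list(zip(rep_codes, ib))))[0]
            self._m_ib = (combo[:, None] == combo[None, :]).astype(float)
        self._comp_outer = None
        self.comp = None
        if spec.has_competition:
            if comp is None:
                raise ValueError("competition covariate values are required")
            self.comp = np.asarray(comp, dtype=float)
            if spec.competition_random:
                self._comp_outer = np.outer(self.comp, self.comp)

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec,
                       amat: pd.DataFrame,
                       comp_col: Optional[str] = None) -> "SpatialGeneticModel":
        """Build from a tree table.

        ``data`` needs tree_id, the trait column, control, rep, iblock,
        row, col, and the competition column for BC/BAC (default
        ``ci_<label>`` or ``comp_col``). Rows with missing trait values
        are dropped; their grid cells simply leave the AR1 index set.
        ``amat`` is the full relationship matrix indexed by id.
        """
        trait = spec.trait
        if trait not in data.columns:
            raise ValueError(f"trait column {trait!r} missing")
        sub = data.loc[data[trait].notna()].reset_index(drop=True)
        y = sub[trait].to_numpy(dtype=float)
        cols = [np.ones(len(sub))]
        names = ["mean"]
        ctrl = sub["control"].to_numpy(dtype=float)
        if len(np.unique(ctrl)) > 1:
            cols.append(ctrl)
            names.append("control")
        comp_vals = None
        if spec.has_competition:
            col = comp_col or f"ci_{spec.competition}"
            if col not in sub.columns:
                raise ValueError(f"competition column {col!r} missing")
            comp_vals = sub[col].to_numpy(dtype=float)
            if not spec.competition_random:
                cols.append(comp_vals)
                names.append(f"beta[{spec.competition}]")
        X = np.column_stack(cols)
        ids = sub["tree_id"].to_numpy()
        a_sub = amat.loc[ids, ids].to_numpy()
        return cls(y, X, spec, amat=a_sub,
                   rep_codes=sub["rep"].to_numpy(),
                   iblock_codes=sub["iblock"].to_numpy(),
                   grid_rows=sub["row"].to_numpy(dtype=int),
                   grid_cols=sub["col"].to_numpy(dtype=int),
                   comp=comp_vals, fe_names=names)

    # ------------------------------------------------------------------
    def _unpack(self, theta: np.ndarray) -> dict:
        vals = {}
        for name, t in zip(self.var_names, theta):
            if name.startswith("rho"):
                vals[name] = _RHO_BOUND * np.tanh(t)
            else:
                vals[name] = np.exp(t)
        return vals

    def _pack(self, vals: dict) -> np.ndarray:
        out = []
        for name in self.var_names:
            v = vals[name]
            if name.startswith("rho"):
                out.append(np.arctanh(np.clip(v / _RHO_BOUND, -0.9999, 0.9999)))
            else:
                out.append(np.log(max(v, 1e-10)))
        return np.array(out)

    def build_cov(self, vc: dict) -> np.ndarray:
        """Marginal covariance V(theta) over the observations."""
        v = vc["sigma2_a"] * self.amat
        if self.spec.spatial:
            # power-table lookup: rho^d for the few distinct grid lags
            pr = np.float64(vc["rho_row"]) ** np.arange(self._dr.max() + 1)
            pc = np.float64(vc["rho_col"]) ** np.arange(self._dc.max() + 1)
            ar1 = pr[self._dr]
            ar1 *= pc[self._dc]
            ar1 *= vc["sigma2_xi"]
            v += ar1
            v.flat[:: self.nobs + 1] += vc["sigma2_eta"]
        else:
            v += vc["sigma2_rep"] * self._m_rep
            v += vc["sigma2_iblock"] * self._m_ib
            v.flat[:: self.nobs + 1] += vc["sigma2_e"]
        if self._comp_outer is not None:
            v += vc["sigma2_comp"] * self._comp_outer
        return v

    def neg2ll(self, theta: np.ndarray) -> float:
        """-2 REML log-likelihood at the transformed parameter vector."""
        if not np.all(np.isfinite(theta)):
            return _BIG
        vc = self._unpack(theta)
        try:
            return reml_neg2ll(self.y, self.X, self.build_cov(vc),
                               overwrite_v=True)
        except (np.linalg.LinAlgError, linalg.LinAlgError, ValueError):
            return _BIG + float(np.sum(theta ** 2))

    # ------------------------------------------------------------------
    def _start_values(self) -> dict:
        beta, *_ = np.linalg.lstsq(self.X, self.y, rcond=None)
        vt = float(np.var(self.y - self.X @ beta, ddof=self.k_fe))
        vt = max(vt, 1e-6)
        vals = {"sigma2_a": 0.3 * vt}
        if self.spec.spatial:
            vals.update(sigma2_xi=0.25 * vt, rho_row=0.3, rho_col=0.3,
                        sigma2_eta=0.45 * vt)
        else:
            vals.update(sigma2_rep=0.1 * vt, sigma2_iblock=0.1 * vt,
                        sigma2_e=0.5 * vt)
        if "sigma2_comp" in self.var_names:
            vals["sigma2_comp"] = 0.1 * vt
        return vals

    def fit(self, start: Optional[dict] = None, n_starts: int = 1,
            seed: int = 0, maxiter: int = 1500, tol: float = 1e-8,
            max_restarts: int = 2, compute_se: bool = True) -> "REMLResults":
        """Maximise the REML likelihood.

        ``n_starts`` > 1 adds randomly perturbed starting points; on
        apparent non-convergence up to ``max_restarts`` further perturbed
        starts are tried before the result is flagged non-converged.
        ``compute_se=False`` skips the numerical Hessian (standard errors
        come back NaN), useful when only the likelihood is needed.
        Deterministic given data, options and seed.
        """
        rng = np.random.default_rng(seed)
        theta0 = self._pack(start or self._start_values())
        starts = [theta0]
        for _ in range(n_starts - 1):
            starts.append(theta0 + rng.normal(0, 0.5, len(theta0)))

        best = None
        attempts = 0
        while True:
            for t0 in starts:
                res = optimize.minimize(
                    self.neg2ll, t0, method="Nelder-Mead",
                    options={"maxiter": maxiter, "xatol": 1e-3, "fatol": tol})
                ref = optimize.minimize(
                    self.neg2ll, res.x, method="L-BFGS-B",
                    options={"maxiter": 200, "ftol": 1e-12, "gtol": 1e-7})
                cand = ref if ref.fun <= res.fun else res
                ok = cand.fun < _BIG and np.all(np.isfinite(cand.x))
                if best is None or cand.fun < best[0].fun - 1e-12:
                    best = (cand, ok)
            if best[1] or attempts >= max_restarts:
                break
            attempts += 1
            starts = [theta0 + rng.normal(0, 1.0, len(theta0))]

        opt, converged = best
        theta = opt.x
        vc = self._unpack(theta)
        n2ll = float(opt.fun)
        converged = converged and n2ll < _BIG

        if compute_se:
            cov_raw, bse = self._param_cov(theta)
        else:
            cov_raw = pd.DataFrame(np.full((len(theta), len(theta)), np.nan),
                                   index=self.var_names, columns=self.var_names)
            bse = {nm: np.nan for nm in self.var_names}
        # fixed effects at the optimum
        V = self.build_cov(vc)
        c = linalg.cho_factor(V, lower=True, check_finite=False)
        vi_x = linalg.cho_solve(c, self.X, check_finite=False)
        xtvix_inv = np.linalg.inv(self.X.T @ vi_x)
        fe = xtvix_inv @ (vi_x.T @ self.y)
        fe_bse = np.sqrt(np.diag(xtvix_inv))
        return REMLResults(model=self, params=vc, bse=bse, cov_params=cov_raw,
                           fe_params=pd.Series(fe, index=self.fe_names),
                           fe_bse=pd.Series(fe_bse, index=self.fe_names),
                           n2ll=n2ll, converged=bool(converged),
                           n_iter=int(opt.nit), theta=theta)

    def _param_cov(self, theta: np.ndarray) -> tuple[pd.DataFrame, dict]:
        """Delta-method covariance of the raw variance parameters."""
        k = len(theta)
        h = 1e-4 * (1.0 + np.abs(theta))
        f0 = self.neg2ll(theta)
        H = np.zeros((k, k))
        for i in range(k):
            ei = np.zeros(k)
            ei[i] = h[i]
            H[i, i] = (self.neg2ll(theta + ei) - 2 * f0 +
                       self.neg2ll(theta - ei)) / h[i] ** 2
            for j in range(i + 1, k):
                ej = np.zeros(k)
                ej[j] = h[j]
                H[i, j] = H[j, i] = (
                    self.neg2ll(theta + ei + ej) - self.neg2ll(theta + ei - ej)
                    - self.neg2ll(theta - ei + ej) + self.neg2ll(theta - ei - ej)
                ) / (4 * h[i] * h[j])
        try:
            cov_t = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_t = 2.0 * np.linalg.pinv(H)
        # jacobian of raw = g(theta)
        vc = self._unpack(theta)
        jac = np.array([
            _RHO_BOUND * (1 - np.tanh(t) ** 2) if nm.startswith("rho") else vc[nm]
            for nm, t in zip(self.var_names, theta)])
        cov_raw = jac[:, None] * cov_t * jac[None, :]
        d = np.diag(cov_raw).copy()
        bad = d < 0
        if bad.any():
            warnings.warn("negative Hessian-based variances; SEs set to NaN")
            d[bad] = np.nan
        bse = dict(zip(self.var_names, np.sqrt(d)))
        return (pd.DataFrame(cov_raw, index=self.var_names,
                             columns=self.var_names), bse)


@dataclass
class REMLResults:
    """REML fit results: components, uncertainties and diagnostics."""

    model: SpatialGeneticModel
    params: dict
    bse: dict
    cov_params: pd.DataFrame = field(repr=False)
    fe_params: pd.Series
    fe_bse: pd.Series
    n2ll: float
    converged: bool
    n_iter: int
    theta: np.ndarray = field(repr=False)

    @property
    def llf(self) -> float:
        """REML log-likelihood."""
        return -0.5 * self.n2ll

    @property
    def t_params(self) -> int:
        """Number of free variance parameters."""
        return len(self.model.var_names)

    @property
    def df_resid(self) -> int:
        """Residual degrees of freedom nu = n - p."""
        return self.model.nobs - self.model.k_fe

    @property
    def residual_variance(self) -> float:
        """The independent residual: units (nugget) under AR1, else iid."""
        return self.params["sigma2_eta" if self.model.spec.spatial else "sigma2_e"]

    def heritability(self) -> tuple[float, float]:
        """Narrow-sense h2 = VarA / (VarA + VarE) with delta-method SE.

        VarE is the units (nugget) component for AR1 models and the iid
        residual otherwise; the spatially correlated component and design
        variances are excluded from the denominator.
        """
        va = self.params["sigma2_a"]
        e_name = "sigma2_eta" if self.model.spec.spatial else "sigma2_e"
        ve = self.params[e_name]
        tot = va + ve
        if tot <= 0:
            raise ZeroDivisionError("heritability undefined: VarA + VarE = 0")
        h2 = va / tot
        g = pd.Series(0.0, index=self.cov_params.index)
        g["sigma2_a"] = ve / tot ** 2
        g[e_name] = -va / tot ** 2
        var = float(g @ self.cov_params @ g)
        return h2, float(np.sqrt(max(var, 0.0)))

    @property
    def h2(self) -> float:
        return self.heritability()[0]

    @property
    def h2_se(self) -> float:
        return self.heritability()[1]

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"REML fit: model {spec.family}, trait {spec.trait}"
            + (f", competition {spec.competition}" if spec.competition else ""),
            f"n = {self.model.nobs}, p = {self.model.k_fe}, "
            f"t = {self.t_params}, nu = {self.df_resid}",
            f"logLik = {self.llf:.4f}   converged = {self.converged}",
            "",
            "Variance components:",
        ]
        for nm in self.model.var_names:
            se = self.bse.get(nm, np.nan)
            lines.append(f"  {nm:<14s} {self.params[nm]:>12.6g}  (SE {se:.4g})")
        lines.append("")
        lines.append("Fixed effects:")
        for nm in self.fe_params.index:
            lines.append(f"  {nm:<14s} {self.fe_params[nm]:>12.6g}  "
                         f"(SE {self.fe_bse[nm]:.4g})")
        try:
            h2, se = self.heritability()
            lines.append("")
            lines.append(f"h2 = {h2:.4f}  (SE {se:.4f})")
        except ZeroDivisionError:
            pass
        return "\n".join(lines)

    def to_dict(self) -> dict:
        h2, h2_se = self.heritability()
        return {
            "family": self.model.spec.family,
            "trait": self.model.spec.trait,
            "competition": self.model.spec.competition,
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "fe_params": {k: float(v) for k, v in self.fe_params.items()},
            "llf": self.llf,
            "t": self.t_params,
            "nu": self.df_resid,
            "h2": h2,
            "h2_se": h2_se,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def heritability(fit: REMLResults) -> tuple[float, float]:
    """Functional alias for :meth:`REMLResults.heritability`."""
    if not fit.converged:
        raise ValueError("heritability requires a converged fit")
    return fit.heritability()
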