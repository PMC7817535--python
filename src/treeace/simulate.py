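"""Synthetic phenotypes, site fields, buffer stands and canopy rasters.

The phenotype generator follows the individual-tree mixed model

    y_i = mu + control_i + rep_i + iblock_i + a_i + beta_c * CI*_i + xi_i + eta_i

with additive genetic values ``a`` drawn on the pedigree, a separable
AR1(rho_row) x AR1(rho_col) site field ``xi`` on the planting grid, iid
noise ``eta``, and a competition penalty proportional to the standardized
Hegyi-type index CI* of the neighbours' baseline sizes. Baseline sizes are
drawn in a single pass (genetic + site + noise around a positive mean)
before the penalty is applied, so competition enters as a fixed mechanism
rather than an iterated growth model. All true effects are retained for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .competition import compute_ci, neighbors_area, radius_for_mean_count, standardize
from .pedigree import Pedigree, gene_drop
from .raster import CHMRaster
from .trial import TrialDesignParams

__all__ = [
    "SimulationParams",
    "CHMParams",
    "compute_volume",
    "ar1_field",
    "simulate_buffer",
    "simulate_trait",
    "simulate_phenotypes",
    "simulate_chm",
    "TRAIT_DEFAULTS",
]

# V182 stem-volume equation constants (DBH in cm, H in m, V in m^3)
V182_A = 1.79068
V182_B = 1.07473
V182_C = -10.03201
BREAST_HEIGHT = 1.4


def compute_volume(dbh, h):
    """Total stem volume by the V182 equation.

    V = DBH^a * (H^2 / (H - 1.4))^b * e^c with DBH in centimetres and H in
    metres; singular at breast height (H = 1.4 m).
    """
    dbh = np.asarray(dbh, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(dbh[~np.isnan(dbh)] <= 0):
        raise ValueError("DBH must be > 0")
    if np.any(h[~np.isnan(h)] <= BREAST_HEIGHT):
        raise ValueError(f"height must exceed breast height ({BREAST_HEIGHT} m)")
    v = dbh ** V182_A * (h ** 2 / (h - BREAST_HEIGHT)) ** V182_B * np.exp(V182_C)
    return v if v.ndim else float(v)


@dataclass(frozen=True)
class SimulationParams:
    """Variance structure of one simulated trait.

    Variances are on the trait scale; ``beta_c`` is the trait change per
    unit of the standardized competition index; ``baseline_mean`` centres
    the positive baseline size used to build that index.
    """

    mu: float = 0.0
    control_effect: float = 0.0
    sigma2_a: float = 1.0
    sigma2_rep: float = 0.0
    sigma2_iblock: float = 0.0
    sigma2_xi: float = 0.0
    sigma2_eta: float = 1.0
    rho_row: float = 0.0
    rho_col: float = 0.0
    beta_c: float = 0.0
    baseline_mean: float = 10.0
    mortality_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("sigma2_a", "sigma2_rep", "sigma2_iblock",
                     "sigma2_xi", "sigma2_eta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("rho_row", "rho_col"):
            if not abs(getattr(self, name)) < 1:
                raise ValueError(f"|{name}| must be < 1")
        if not 0 <= self.mortality_rate < 1:
            raise ValueError("mortality_rate must be in [0, 1)")


def ar1_field(n_rows: int, n_cols: int, rho_row: float, rho_col: float,
              rng: np.random.Generator) -> np.ndarray:
    """Draw one unit-variance separable AR1 x AR1 Gaussian field.

    Exact simulation via the Kronecker-structured Cholesky factors:
    field = L_row @ Z @ L_col' where L are Cholesky factors of the row and
    column AR1 correlation matrices.
    """
    from .models import ar1_corr

    lr = np.linalg.cholesky(ar1_corr(n_rows, rho_row))
    lc = np.linalg.cholesky(ar1_corr(n_cols, rho_col))
    z = rng.standard_normal((n_rows, n_cols))
    return lr @ z @ lc.T


def simulate_buffer(params: TrialDesignParams, extent: tuple[float, float],
                    seed: int, height_mean: float = 8.0,
                    height_sd: float = 1.2) -> pd.DataFrame:
    """Poisson-thinned buffer stand on the continued planting lattice.

    The buffer ring of width ``buffer_width`` surrounds the trial extent
    (0..width, 0..height); lattice points are kept with probability
    density * spacing^2 / 10^4 to realise ``buffer_density`` stems/ha.
    Buffer trees carry positions and heights only (no pedigree, no
    phenotype records).
    """
    rng = np.random.default_rng(seed)
    s = params.spacing
    w, h = extent
    bw = params.buffer_width
    if bw <= 0:
        return pd.DataFrame(columns=["x", "y", "H"])
    cols = np.arange(int(np.floor(-bw / s)), int(np.ceil((w + bw) / s)) + 1)
    rows = np.arange(int(np.floor(-bw / s)), int(np.ceil((h + bw) / s)) + 1)
    cc, rr = np.meshgrid(cols, rows)
    x = cc.ravel() * s
    y = rr.ravel() * s
    inside = (x >= -1e-9) & (x <= w - s + 1e-9) & (y >= -1e-9) & (y <= h - s + 1e-9)
    x, y = x[~inside], y[~inside]
    keep_p = min(1.0, params.buffer_density * s * s / 10_000.0)
    keep = rng.random(len(x)) < keep_p
    return pd.DataFrame({
        "x": x[keep], "y": y[keep],
        "H": rng.normal(height_mean, height_sd, keep.sum()),
    })


def simulate_trait(trees: pd.DataFrame, pedigree: Pedigree,
                   sim: SimulationParams, seed: int, *, spacing: float,
                   buffer: pd.DataFrame | None = None,
                   radius: float | None = None) -> pd.DataFrame:
    """Simulate one trait on the trial; returns per-tree values and truth.

    ``trees`` must hold the complete grid (tree_id, family, control, rep,
    iblock, row, col, x, y, alive). Dead trees get NaN trait values but
    their true effects are still recorded; dead trees and buffer trees do
    not receive phenotypes, and dead trees are excluded as competitors.

    Output columns: y, true_a, true_site, true_ci (standardized index),
    true_comp (beta_c * true_ci), baseline.
    """
    rng = np.random.default_rng(seed)
    n = len(trees)
    rows = trees["row"].to_numpy()
    cols = trees["col"].to_numpy()
    n_rows, n_cols = rows.max() + 1, cols.max() + 1
    alive = trees["alive"].to_numpy(dtype=bool)

    a = gene_drop(pedigree, sim.sigma2_a, rng).reindex(trees["tree_id"]).to_numpy()

    reps = trees["rep"].to_numpy()
    rep_levels = np.unique(reps)
    rep_eff = dict(zip(rep_levels,
                       rng.normal(0, np.sqrt(sim.sigma2_rep), len(rep_levels))))
    ib_keys = list(dict.fromkeys(zip(reps, trees["iblock"].to_numpy())))
    ib_eff = dict(zip(ib_keys, rng.normal(0, np.sqrt(sim.sigma2_iblock), len(ib_keys))))

    field = ar1_field(n_rows, n_cols, sim.rho_row, sim.rho_col, rng)
    xi = np.sqrt(sim.sigma2_xi) * field[rows, cols]
    eta = rng.normal(0, np.sqrt(sim.sigma2_eta), n)

    # single-pass competition: baseline sizes first, then the penalty.
    # Baselines are drawn independently of the trait's own effects so the
    # covariate is exogenous and the true coefficient is recoverable.
    ci_std = np.zeros(n)
    size_sd = np.sqrt(sim.sigma2_a + sim.sigma2_xi + sim.sigma2_eta)
    baseline = sim.baseline_mean + rng.normal(0, size_sd, n)
    baseline = np.clip(baseline, 0.1, None)
    if sim.beta_c != 0.0:
        if radius is None:
            radius = radius_for_mean_count(spacing, 20)
        pos = trees[["x", "y"]].to_numpy()
        sizes = baseline
        active = alive
        if buffer is not None and len(buffer):
            bpos = buffer[["x", "y"]].to_numpy()
            total_var = sim.sigma2_a + sim.sigma2_xi + sim.sigma2_eta
            bsize = np.clip(sim.baseline_mean +
                            rng.normal(0, np.sqrt(total_var), len(buffer)), 0.1, None)
            pos = np.vstack([pos, bpos])
            sizes = np.concatenate([sizes, bsize])
            active = np.concatenate([active, np.ones(len(buffer), dtype=bool)])
        subject = np.zeros(len(sizes), dtype=bool)
        subject[:n] = alive
        adj = neighbors_area(pos, radius, active=active)
        tab = compute_ci(sizes, pos, adj, "CIA", subject=subject)
        raw = tab["ci"].to_numpy()[:n]
        std = np.zeros(n)
        std[alive] = standardize(raw[alive])
        ci_std = std

    rep_v = np.array([rep_eff[r] for r in reps])
    ib_v = np.array([ib_eff[(r, b)] for r, b in zip(reps, trees["iblock"])])
    control = trees["control"].to_numpy(dtype=bool).astype(float)

    y = (sim.mu + sim.control_effect * control + rep_v + ib_v +
         a + sim.beta_c * ci_std + xi + eta)
    y = np.where(alive, y, np.nan)
    return pd.DataFrame({
        "tree_id": trees["tree_id"].to_numpy(),
        "y": y,
        "true_a": a,
        "true_site": xi,
        "true_ci": ci_std,
        "true_comp": sim.beta_c * ci_std,
        "baseline": baseline,
    })


#: realistic per-trait defaults for an age-7 radiata pine progeny trial:
#: H in m, DBH in cm, D38 in percent needle loss, A in km/s.
TRAIT_DEFAULTS: dict[str, SimulationParams] = {
    "H": SimulationParams(mu=8.0, control_effect=0.3, sigma2_a=0.5,
                          sigma2_rep=0.2, sigma2_iblock=0.1, sigma2_xi=0.5,
                          sigma2_eta=0.7, rho_row=0.6, rho_col=0.6,
                          beta_c=-0.25, baseline_mean=8.0),
    "DBH": SimulationParams(mu=13.0, control_effect=0.5, sigma2_a=2.0,
                            sigma2_rep=0.8, sigma2_iblock=0.4, sigma2_xi=2.0,
                            sigma2_eta=3.0, rho_row=0.6, rho_col=0.6,
                            beta_c=-0.9, baseline_mean=13.0),
    "D38": SimulationParams(mu=30.0, control_effect=-3.0, sigma2_a=60.0,
                            sigma2_rep=20.0, sigma2_iblock=10.0, sigma2_xi=150.0,
                            sigma2_eta=100.0, rho_row=0.75, rho_col=0.75,
                            beta_c=3.0, baseline_mean=30.0),
    "A": SimulationParams(mu=2.6, control_effect=0.02, sigma2_a=0.02,
                          sigma2_rep=0.004, sigma2_iblock=0.002, sigma2_xi=0.008,
                          sigma2_eta=0.02, rho_row=0.5, rho_col=0.5,
                          beta_c=0.01, baseline_mean=2.6),
}


def simulate_phenotypes(trees: pd.DataFrame, pedigree: Pedigree, seed: int, *,
                        spacing: float, buffer: pd.DataFrame | None = None,
                        trait_params: dict[str, SimulationParams] | None = None
                        ) -> pd.DataFrame:
    """Simulate the five-trait phenotype table (H, DBH, V, D38, A).

    Each trait is drawn independently from its own variance structure
    (genetic correlations between traits are not modelled); V is derived
    deterministically from DBH and H via V182; D38 is a latent Gaussian
    clipped to [0, 100] and rounded to 5% steps. True effects for each
    simulated trait are returned in ``<trait>_true_*`` columns.
    """
    params = dict(TRAIT_DEFAULTS)
    if trait_params:
        params.update(trait_params)
    out = trees.copy().reset_index(drop=True)
    for k, trait in enumerate(("H", "DBH", "D38", "A")):
        sim = params[trait]
        res = simulate_trait(out, pedigree, sim, seed + 101 * (k + 1),
                             spacing=spacing, buffer=buffer)
        vals = res["y"].to_numpy()
        if trait == "H":
            vals = np.clip(vals, 1.6, None)
        elif trait == "DBH":
            vals = np.clip(vals, 1.0, None)
        elif trait == "D38":
            vals = np.clip(vals, 0.0, 100.0)
            vals = np.round(vals / 5.0) * 5.0
        out[trait] = vals
        for c in ("true_a", "true_site", "true_ci"):
            out[f"{trait}_{c}"] = res[c].to_numpy()
    with np.errstate(invalid="ignore"):
        alive = out["alive"].to_numpy(dtype=bool)
        v = np.full(len(out), np.nan)
        v[alive] = compute_volume(out.loc[alive, "DBH"], out.loc[alive, "H"])
        out["V"] = v
    return out


@dataclass(frozen=True)
class CHMParams:
    """Rendering parameters for the synthetic canopy height model."""

    resolution: float = 0.25
    crown_shape: float = 1.5       # exponent of the generalized cone profile
    crown_ratio: float = 0.22      # crown radius as a fraction of height
    crown_radius_min: float = 0.6
    crown_radius_max: float = 2.6
    noise_sd: float = 0.0
    pit_rate: float = 0.0
    pit_depth: float = 0.8         # fractional height loss at a pit cell
    margin: float = 0.0            # extra metres around the tree bounding box

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if not 0 <= self.pit_rate < 1:
            raise ValueError("pit_rate must be in [0, 1)")


def simulate_chm(trees: pd.DataFrame, params: CHMParams, seed: int = 0) -> CHMRaster:
    """Render a CHM as the per-cell maximum over generalized-cone crowns.

    ``trees`` needs x, y, H columns (live trees, trial and buffer alike);
    an optional crown_radius column overrides the height-proportional
    default. Additive Gaussian noise and random single-cell pits are
    applied at the configured rates; ground cells are 0.
    """
    rng = np.random.default_rng(seed)
    cs = params.resolution
    live = trees.dropna(subset=["H"])
    if len(live) == 0:
        raise ValueError("no trees with heights to render")
    x = live["x"].to_numpy(dtype=float)
    y = live["y"].to_numpy(dtype=float)
    h = live["H"].to_numpy(dtype=float)
    if "crown_radius" in live.columns:
        r = live["crown_radius"].to_numpy(dtype=float)
    else:
        r = np.clip(params.crown_ratio * h, params.crown_radius_min,
                    params.crown_radius_max)

    m = params.margin + r.max() + cs
    x0, y1 = x.min() - m, y.max() + m
    ncols = int(np.ceil((x.max() + m - x0) / cs))
    nrows = int(np.ceil((y1 - (y.min() - m)) / cs))
    canvas = np.zeros((nrows, ncols))

    for xi_, yi_, hi, ri in zip(x, y, h, r):
        half = int(np.ceil(ri / cs)) + 1
        ci = int((xi_ - x0) / cs)
        rj = int((y1 - yi_) / cs)
        r0, r1_ = max(0, rj - half), min(nrows, rj + half + 1)
        c0, c1_ = max(0, ci - half), min(ncols, ci + half + 1)
        if r0 >= r1_ or c0 >= c1_:
            continue
        cx = x0 + (np.arange(c0, c1_) + 0.5) * cs
        cy = y1 - (np.arange(r0, r1_) + 0.5) * cs
        dist = np.hypot(cx[None, :] - xi_, cy[:, None] - yi_)
        surf = hi * np.clip(1.0 - (dist / ri) ** params.crown_shape, 0.0, None)
        np.maximum(canvas[r0:r1_, c0:c1_], surf, out=canvas[r0:r1_, c0:c1_])

    if params.noise_sd > 0:
        canopy = canvas > 0
        canvas[canopy] += rng.normal(0, params.noise_sd, canopy.sum())
        canvas = np.clip(canvas, 0, None)
    if params.pit_rate > 0:
        pits = rng.random(canvas.shape) < params.pit_rate
        canvas[pits] *= (1.0 - params.pit_depth)
    return CHMRaster(values=canvas, cell_size=cs, origin=(x0, y1))
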